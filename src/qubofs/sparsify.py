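"""Hardware-motivated problem reductions: block subsampling and coupling
thresholding.

These shrink a pixel-selection QUBO to annealer-embeddable size: keep the
highest-importance pixel of each non-overlapping image block (default 2x2,
784 -> 196 variables for 28x28 images), then keep only the ``m``
largest-magnitude couplings (default 2000).  Thresholding is applied to the
pre-penalty objective; the linear cardinality penalty is diagonal, so adding
it before or after thresholding yields the same problem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .data import FlatDataset
from .exceptions import DimensionError
from .qubo import QuboProblem

DEFAULT_BLOCK = (2, 2)
DEFAULT_N_COUPLINGS = 2000

__all__ = [
    "SubsampleMap",
    "subsample_by_importance",
    "restrict_dataset",
    "threshold_couplings",
]


@dataclass(frozen=True)
class SubsampleMap:
    """One kept flat pixel index per image block, in row-major block order."""

    block: tuple[int, int]
    kept_indices: tuple[int, ...]
    reduced_shape: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "block", tuple(self.block))
        object.__setattr__(self, "kept_indices", tuple(int(i) for i in self.kept_indices))
        object.__setattr__(self, "reduced_shape", tuple(self.reduced_shape))
        hr, wr = self.reduced_shape
        if len(self.kept_indices) != hr * wr:
            raise DimensionError("kept_indices length must equal the reduced grid size")

    @property
    def n_reduced(self) -> int:
        return len(self.kept_indices)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "block": list(self.block),
                "kept_indices": list(self.kept_indices),
                "reduced_shape": list(self.reduced_shape),
            }
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SubsampleMap":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            source = Path(source).read_text()
        payload = json.loads(source)
        return cls(
            block=tuple(payload["block"]),
            kept_indices=tuple(payload["kept_indices"]),
            reduced_shape=tuple(payload["reduced_shape"]),
        )


def subsample_by_importance(
    importance: np.ndarray,
    shape: tuple[int, int],
    block: tuple[int, int] = DEFAULT_BLOCK,
) -> SubsampleMap:
    """Keep the highest-importance pixel of each non-overlapping block.

    Ties within a block are broken toward the smallest flat index, so the
    result is deterministic.
    """
    h, w = shape
    br, bc = block
    importance = np.asarray(importance, dtype=float)
    if importance.shape != (h * w,):
        raise DimensionError(
            f"importance must have length H*W={h * w}; got {importance.shape}"
        )
    if h % br != 0:
        raise DimensionError(f"image height {h} not divisible by block rows {br}")
    if w % bc != 0:
        raise DimensionError(f"image width {w} not divisible by block cols {bc}")
    grid = importance.reshape(h, w)
    # (hr, wr, br*bc) with within-block entries in row-major (= flat-index) order,
    # so argmax's first-maximum rule is exactly the smallest-flat-index tie-break.
    blocks = (
        grid.reshape(h // br, br, w // bc, bc)
        .transpose(0, 2, 1, 3)
        .reshape(h // br, w // bc, br * bc)
    )
    within = blocks.argmax(axis=2)
    block_rows, block_cols = np.meshgrid(
        np.arange(h // br), np.arange(w // bc), indexing="ij"
    )
    rows = block_rows * br + within // bc
    cols = block_cols * bc + within % bc
    kept = (rows * w + cols).reshape(-1)
    return SubsampleMap(
        block=(br, bc),
        kept_indices=tuple(int(i) for i in kept),
        reduced_shape=(h // br, w // bc),
    )


def restrict_dataset(fd: FlatDataset, sm: SubsampleMap) -> FlatDataset:
    """Project a flat dataset onto the kept columns; ``coord_map`` keeps
    reporting original image coordinates."""
    kept = list(sm.kept_indices)
    if kept and (min(kept) < 0 or max(kept) >= fd.n_features):
        raise DimensionError("subsample map index out of range for this dataset")
    return FlatDataset(
        features=fd.features[:, kept],
        labels=fd.labels,
        coord_map=tuple(fd.coord_map[i] for i in kept),
        image_shape=fd.image_shape,
    )


def threshold_couplings(q: QuboProblem, m: int = DEFAULT_N_COUPLINGS) -> QuboProblem:
    """Keep only the ``m`` largest-magnitude couplings.

    Diagonal and offset are untouched.  Ties at the magnitude cutoff are
    broken by lexicographic ``(i, j)`` order (smaller pairs kept first) so
    runs are reproducible.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if m >= q.n_couplings:
        return replace(q, quadratic=dict(q.quadratic))
    ranked = sorted(q.quadratic.items(), key=lambda item: (-abs(item[1]), item[0]))
    return replace(q, quadratic=dict(ranked[:m]))
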