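"""Quantile discretization and mutual-information estimation.

Features are discretized into (by default 20) quantile bins; importance is
the MI of each binned feature with the class label, redundancy the pairwise
MI between binned features.  All MI values are in nats (natural log): the
log base only rescales the assembled objective uniformly and cannot change
its argmin.  Terms with zero joint probability contribute 0, and no
small-sample bias correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .data import FlatDataset
from .exceptions import DimensionError, FormatError

DEFAULT_N_BINS = 20

__all__ = [
    "DiscretizedDataset",
    "ProbabilityTables",
    "MIMatrices",
    "discretize",
    "estimate_importance",
    "estimate_redundancy",
    "estimate_mi_matrices",
    "save_mi",
    "load_mi",
]


@dataclass(frozen=True)
class DiscretizedDataset:
    """Per-feature quantile bin indices plus the edges that produced them.

    ``bins[i, j]`` is the number of retained edges of feature ``j`` strictly
    below sample ``i``'s value.  Duplicate quantile edges (common with
    discrete pixel intensities) are merged, so the effective bin count of a
    feature may be below ``n_bins``; a constant feature has exactly one
    effective bin.
    """

    bins: np.ndarray  # (N, n) int
    bin_edges: tuple[np.ndarray, ...]  # per-feature sorted cut points
    labels: np.ndarray  # (N,)
    n_bins: int = DEFAULT_N_BINS

    @property
    def n_features(self) -> int:
        return self.bins.shape[1]

    @property
    def n_samples(self) -> int:
        return self.bins.shape[0]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def effective_bins(self) -> tuple[int, ...]:
        return tuple(len(edges) + 1 for edges in self.bin_edges)

    def restrict(self, columns: Iterable[int]) -> "DiscretizedDataset":
        """Keep only the given feature columns (bin indices are unchanged)."""
        cols = list(columns)
        return DiscretizedDataset(
            bins=self.bins[:, cols],
            bin_edges=tuple(self.bin_edges[j] for j in cols),
            labels=self.labels,
            n_bins=self.n_bins,
        )


@dataclass(frozen=True)
class MIMatrices:
    """Importance vector and (sparse, upper-triangular) redundancy values.

    ``redundancy`` stores MI values only for pairs ``i < j``; symmetry is
    implied.  A pipeline that sparsifies before scoring need not populate
    every pair.
    """

    importance: np.ndarray  # (n,) MI(x_i, y) in nats, >= 0
    redundancy: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "importance", np.asarray(self.importance, dtype=float))
        for (i, j) in self.redundancy:
            if not (0 <= i < j < self.n):
                raise DimensionError(f"redundancy key {(i, j)} violates 0 <= i < j < n")

    @property
    def n(self) -> int:
        return self.importance.shape[0]

    def redundancy_matrix(self) -> np.ndarray:
        """Dense symmetric redundancy matrix with zero diagonal."""
        mat = np.zeros((self.n, self.n))
        for (i, j), value in self.redundancy.items():
            mat[i, j] = mat[j, i] = value
        return mat


def _quantile_edges(column: np.ndarray, n_bins: int) -> np.ndarray:
    """Interior quantile cut points with duplicates and vacuous edges removed.

    An edge at or below the column minimum (or above the maximum) would
    create a structurally empty bin, so such edges are dropped; a constant
    column therefore yields no edges at all.
    """
    probs = np.arange(1, n_bins) / n_bins
    edges = np.unique(np.quantile(column, probs))
    lo, hi = column.min(), column.max()
    return edges[(edges > lo) & (edges <= hi)]


def discretize(fd: FlatDataset, n_bins: int = DEFAULT_N_BINS) -> DiscretizedDataset:
    """Quantile-bin every feature column of ``fd``.

    The bin index of a value is the count of retained edges strictly below
    it, so indices run from 0 to the per-feature effective bin count minus 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if fd.n_samples < 2:
        raise ValueError("need at least 2 samples to discretize")
    n = fd.n_features
    bins = np.empty((fd.n_samples, n), dtype=np.int64)
    all_edges: list[np.ndarray] = []
    for j in range(n):
        column = fd.features[:, j]
        edges = _quantile_edges(column, n_bins)
        bins[:, j] = np.searchsorted(edges, column, side="left")
        all_edges.append(edges)
    return DiscretizedDataset(
        bins=bins, bin_edges=tuple(all_edges), labels=fd.labels, n_bins=n_bins
    )


class ProbabilityTables:
    """Empirical joint/marginal probability tables of a discretized dataset.

    Pairwise joints are computed on demand as 2-D histograms — the identical
    estimator to marginalizing the (intractable) full joint.
    """

    def __init__(self, dd: DiscretizedDataset):
        self._dd = dd

    def joint_feature_label(self, i: int) -> np.ndarray:
        dd = self._dd
        nb = dd.effective_bins[i]
        counts = np.bincount(
            dd.bins[:, i] * dd.n_classes + dd.labels, minlength=nb * dd.n_classes
        ).reshape(nb, dd.n_classes)
        return counts / dd.n_samples

    def joint_feature_pair(self, i: int, j: int) -> np.ndarray:
        dd = self._dd
        nbi, nbj = dd.effective_bins[i], dd.effective_bins[j]
        counts = np.bincount(
            dd.bins[:, i] * nbj + dd.bins[:, j], minlength=nbi * nbj
        ).reshape(nbi, nbj)
        return counts / dd.n_samples

    def marginal_feature(self, i: int) -> np.ndarray:
        return self.joint_feature_label(i).sum(axis=1)

    def marginal_label(self) -> np.ndarray:
        dd = self._dd
        return np.bincount(dd.labels, minlength=dd.n_classes) / dd.n_samples


def _mi_from_counts(counts: np.ndarray) -> float:
    """MI in nats from a 2-D contingency table of counts; 0*log0 := 0."""
    total = counts.sum()
    if total == 0:
        raise ValueError("empty contingency table")
    joint = counts / total
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nonzero = joint > 0
    terms = np.zeros_like(joint)
    terms[nonzero] = joint[nonzero] * (
        np.log(joint[nonzero]) - np.log((px @ py)[nonzero])
    )
    value = float(terms.sum())
    # Estimated MI is nonnegative up to float round-off; clamp tiny negatives.
    if value < -1e-9:
        raise AssertionError(f"MI estimate {value} below clamping tolerance")
    return max(value, 0.0)


def estimate_importance(dd: DiscretizedDataset) -> np.ndarray:
    """MI(x_i, y) in nats for every feature, from bin/label contingency tables."""
    if dd.n_samples == 0:
        raise ValueError("empty dataset")
    n_classes = dd.n_classes
    out = np.empty(dd.n_features)
    for j in range(dd.n_features):
        nb = dd.effective_bins[j]
        counts = np.bincount(
            dd.bins[:, j] * n_classes + dd.labels, minlength=nb * n_classes
        ).reshape(nb, n_classes)
        out[j] = _mi_from_counts(counts)
    return out


def estimate_redundancy(
    dd: DiscretizedDataset,
    pairs: Iterable[tuple[int, int]] | None = None,
) -> dict[tuple[int, int], float]:
    """Pairwise MI(x_i, x_j) in nats for the requested pairs (default: all i<j).

    Each value is estimated from the 2-D joint histogram of the two bin
    columns, which is exactly the pair marginal of the full empirical joint.
    """
    n = dd.n_features
    if pairs is None:
        pairs = ((i, j) for i in range(n) for j in range(i + 1, n))
    eff = dd.effective_bins
    out: dict[tuple[int, int], float] = {}
    for (i, j) in pairs:
        if not (0 <= i < n and 0 <= j < n):
            raise DimensionError(f"pair {(i, j)} out of range for n={n}")
        if i >= j:
            raise DimensionError(f"pair {(i, j)} must satisfy i < j")
        counts = np.bincount(
            dd.bins[:, i] * eff[j] + dd.bins[:, j], minlength=eff[i] * eff[j]
        ).reshape(eff[i], eff[j])
        out[(i, j)] = _mi_from_counts(counts)
    return out


def estimate_mi_matrices(
    dd: DiscretizedDataset,
    pairs: Iterable[tuple[int, int]] | None = None,
) -> MIMatrices:
    """Convenience wrapper computing importance and redundancy together."""
    return MIMatrices(
        importance=estimate_importance(dd),
        redundancy=estimate_redundancy(dd, pairs),
    )


def save_mi(mi: MIMatrices, path: str | Path) -> None:
    """Cache MI matrices as a compressed archive (COO triplets for redundancy)."""
    keys = np.array(sorted(mi.redundancy), dtype=np.int64).reshape(-1, 2)
    values = np.array([mi.redundancy[tuple(k)] for k in keys], dtype=float)
    np.savez_compressed(
        Path(path), importance=mi.importance, pair_index=keys, pair_value=values
    )


def load_mi(path: str | Path) -> MIMatrices:
    with np.load(Path(path)) as archive:
        for key in ("importance", "pair_index", "pair_value"):
            if key not in archive:
                raise FormatError(f"MI archive missing key {key!r}")
        redundancy = {
            (int(i), int(j)): float(v)
            for (i, j), v in zip(archive["pair_index"], archive["pair_value"])
        }
        return MIMatrices(importance=archive["importance"], redundancy=redundancy)
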