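"""Comparison selectors: random, evenly spaced grid, and L1-coefficient
ranking, plus thin adapters for transformed-feature compressors (sparse PCA
and a learned bottleneck), which produce k-dimensional codes rather than
pixel masks and are evaluated only through the reconstruction module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import FlatDataset
from .exceptions import SpecError
from .solvers import SelectionMask

__all__ = [
    "BaselineSpec",
    "select_random",
    "select_grid",
    "select_by_coefficients",
    "SparsePcaCoder",
]

KNOWN_METHODS = ("random", "sampled", "lasso", "spca", "autoencoder")


@dataclass(frozen=True)
class BaselineSpec:
    method: str
    k: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in KNOWN_METHODS:
            raise SpecError(f"unknown baseline {self.method!r}; known: {KNOWN_METHODS}")


def select_random(n: int, k: int, seed: int = 0) -> SelectionMask:
    """Uniform sample of k of n features without replacement."""
    if k > n:
        raise ValueError(f"cannot select k={k} of n={n} features")
    rng = np.random.default_rng(seed)
    bits = np.zeros(n, dtype=np.int8)
    bits[rng.choice(n, size=k, replace=False)] = 1
    return SelectionMask(bits)


def _lattice(size: int, g: int) -> np.ndarray:
    """g equally spaced, de-duplicated integer positions over [0, size-1]."""
    return np.unique(np.rint(np.linspace(0, size - 1, g)).astype(int))


def select_grid(shape: tuple[int, int], k: int) -> SelectionMask:
    """Evenly spread k pixels over the image in a grid-like pattern.

    Placement rule (deterministic, no seed): take ``g = round(sqrt(k))``
    equally spaced positions per axis (``linspace`` over ``[0, size-1]``,
    rounded) and form their product lattice in raster order.  If the lattice
    is too large, points are dropped from the end of the raster order; if
    too small, the per-axis count is grown and the extra product points are
    appended in raster order until exactly k remain.
    """
    h, w = shape
    if k > h * w:
        raise ValueError(f"cannot place k={k} pixels on a {h}x{w} grid")
    bits = np.zeros(h * w, dtype=np.int8)
    if k == 0:
        return SelectionMask(bits)
    g = max(1, int(round(np.sqrt(k))))
    points: list[int] = []
    chosen: set[int] = set()
    while len(points) < k:
        rows, cols = _lattice(h, g), _lattice(w, g)
        for r in rows:
            for c in cols:
                flat = int(r * w + c)
                if flat not in chosen:
                    chosen.add(flat)
                    points.append(flat)
        g += 1
    bits[points[:k]] = 1
    return SelectionMask(bits)


def select_by_coefficients(
    fd: FlatDataset,
    k: int,
    *,
    c_init: float = 1.0,
    max_doublings: int = 30,
    max_iter: int = 2000,
) -> SelectionMask:
    """Top-k features by absolute L1-regularized coefficient magnitude.

    Features are standardized and a one-vs-rest L1 logistic model is fit;
    features are ranked by the maximum |coefficient| across classes.  The
    regularization strength is relaxed by doubling until at least k features
    have a nonzero coefficient, so the rank cutoff is well defined.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.multiclass import OneVsRestClassifier
    from sklearn.preprocessing import StandardScaler

    labels = np.asarray(fd.labels)
    if np.unique(labels).size < 2:
        raise ValueError("coefficient-based selection needs at least two classes")
    if k > fd.n_features:
        raise ValueError(f"cannot select k={k} of n={fd.n_features} features")

    x = StandardScaler().fit_transform(fd.features)
    c = c_init
    coef = None
    for _ in range(max_doublings):
        base = LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=c, max_iter=max_iter, tol=1e-6
        )
        model = (
            base
            if np.unique(labels).size == 2
            else OneVsRestClassifier(base)
        )
        model.fit(x, labels)
        coef = (
            model.coef_
            if hasattr(model, "coef_")
            else np.vstack([est.coef_ for est in model.estimators_])
        )
        if int((np.abs(coef).max(axis=0) > 0).sum()) >= k:
            break
        c *= 2.0
    assert coef is not None
    scores = np.abs(coef).max(axis=0)
    # stable top-k: sort by (-score, index)
    order = np.lexsort((np.arange(scores.size), -scores))
    bits = np.zeros(fd.n_features, dtype=np.int8)
    bits[order[:k]] = 1
    return SelectionMask(bits)


class SparsePcaCoder:
    """Thin adapter around sparse PCA producing k-dimensional codes.

    Produces transformed features, not a pixel mask; evaluate through the
    reconstruction trainer by feeding codes instead of masked pixels.
    """

    def __init__(self, k: int, seed: int = 0, max_iter: int = 200):
        from sklearn.decomposition import MiniBatchSparsePCA

        self._model = MiniBatchSparsePCA(
            n_components=k, random_state=seed, max_iter=max_iter
        )
        self.k = k

    def fit(self, features: np.ndarray) -> "SparsePcaCoder":
        self._model.fit(features)
        return self

    def encode(self, features: np.ndarray) -> np.ndarray:
        return self._model.transform(features)
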