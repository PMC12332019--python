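"""QUBO assembly, cardinality penalties, energies, and Ising conversion.

The selection objective is ``E(x) = sum_i Q_ii x_i + sum_{i<j} Q_ij x_i x_j
+ offset`` over binary masks.  It is assembled additively from the MI
matrices (``Q = -I + R``) plus either a quadratic cardinality penalty
``alpha * (sum_i x_i - k)^2`` (fully connected) or a uniform linear diagonal
offset ``alpha_l`` (sparsity-preserving).

Note on the quadratic penalty: expanding ``alpha * (sum x_i - k)^2`` gives
diagonal ``alpha * (1 - 2k)``, off-diagonal ``2 * alpha`` per unordered
pair, and constant ``alpha * k^2``.  This expansion — the only form under
which the penalty vanishes exactly at Hamming weight ``k`` — is what this
module implements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import DimensionError, SpecError
from .mi import MIMatrices

__all__ = [
    "QuboProblem",
    "IsingProblem",
    "SelectionSpec",
    "QuadraticConstraintSpec",
    "LinearPenaltySpec",
    "build_mi_qubo",
    "add_quadratic_constraint",
    "add_linear_penalty",
    "to_ising",
    "energy",
]


@dataclass(frozen=True)
class SelectionSpec:
    """Choose exactly ``k`` of ``n`` features."""

    k: int
    n: int

    def __post_init__(self) -> None:
        if not (0 < self.k < self.n):
            raise SpecError(f"need 0 < k < n; got k={self.k}, n={self.n}")


@dataclass(frozen=True)
class QuadraticConstraintSpec:
    alpha: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise SpecError("quadratic penalty weight alpha must be > 0")


@dataclass(frozen=True)
class LinearPenaltySpec:
    """Uniform diagonal offset; sign determines whether selection is
    discouraged (positive) or encouraged (negative)."""

    alpha_l: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha_l):
            raise SpecError("alpha_l must be finite")


@dataclass(frozen=True)
class QuboProblem:
    """Sparse binary-quadratic objective with exact offset bookkeeping.

    ``linear[i]`` holds the diagonal coefficient Q_ii; ``quadratic`` maps
    upper-triangular pairs ``(i, j)`` with ``i < j`` to Q_ij.
    """

    n: int
    linear: np.ndarray
    quadratic: dict[tuple[int, int], float] = field(default_factory=dict)
    offset: float = 0.0

    def __post_init__(self) -> None:
        linear = np.asarray(self.linear, dtype=float)
        if linear.shape != (self.n,):
            raise DimensionError(
                f"linear must have shape ({self.n},); got {linear.shape}"
            )
        for (i, j) in self.quadratic:
            if not (0 <= i < j < self.n):
                raise DimensionError(
                    f"quadratic key {(i, j)} violates 0 <= i < j < n={self.n}"
                )
        object.__setattr__(self, "linear", linear)

    @property
    def n_couplings(self) -> int:
        return len(self.quadratic)

    def energy(self, mask: np.ndarray) -> float:
        return energy(self, mask)

    def dense_symmetric(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(linear, S)`` with S the symmetric zero-diagonal coupling
        matrix, so that ``E(x) = linear @ x + x @ S @ x / 2 + offset``."""
        s = np.zeros((self.n, self.n))
        for (i, j), value in self.quadratic.items():
            s[i, j] = s[j, i] = value
        return self.linear.copy(), s

    def dense_upper(self) -> np.ndarray:
        """Dense Q with the diagonal on the diagonal and couplings above it."""
        q = np.diag(self.linear).astype(float)
        for (i, j), value in self.quadratic.items():
            q[i, j] = value
        return q

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n": self.n,
            "linear": self.linear.tolist(),
            "quadratic": [[i, j, v] for (i, j), v in sorted(self.quadratic.items())],
            "offset": self.offset,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "QuboProblem":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text()
        payload = json.loads(source)
        return cls(
            n=payload["n"],
            linear=np.asarray(payload["linear"], dtype=float),
            quadratic={(int(i), int(j)): float(v) for i, j, v in payload["quadratic"]},
            offset=float(payload.get("offset", 0.0)),
        )

    def to_coo_text(self) -> str:
        """Flat ``i j value`` text form (diagonal entries as ``i == j``)."""
        lines = [f"{i} {i} {v!r}" for i, v in enumerate(self.linear) if v != 0.0]
        lines += [
            f"{i} {j} {v!r}" for (i, j), v in sorted(self.quadratic.items())
        ]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class IsingProblem:
    """Spin-space twin of a QUBO; ``spin_domain`` is ``"pm1"`` for spins in
    {-1, +1} or ``"half"`` for {-1/2, +1/2}."""

    n: int
    h: np.ndarray
    J: dict[tuple[int, int], float]
    offset: float
    spin_domain: str = "pm1"

    _SPINS = {"pm1": (-1.0, 1.0), "half": (-0.5, 0.5)}

    def __post_init__(self) -> None:
        if self.spin_domain not in self._SPINS:
            raise SpecError(f"unknown spin domain {self.spin_domain!r}")
        object.__setattr__(self, "h", np.asarray(self.h, dtype=float))

    def energy(self, spins: np.ndarray) -> float:
        spins = np.asarray(spins, dtype=float)
        down, up = self._SPINS[self.spin_domain]
        if not np.all(np.isin(spins, (down, up))):
            raise ValueError(f"spins must be in {{{down}, {up}}}")
        total = float(self.h @ spins) + self.offset
        for (i, j), value in self.J.items():
            total += value * spins[i] * spins[j]
        return total

    def spins_from_mask(self, mask: np.ndarray) -> np.ndarray:
        down, up = self._SPINS[self.spin_domain]
        return np.where(np.asarray(mask) > 0, up, down)


def build_mi_qubo(mi: MIMatrices) -> QuboProblem:
    """Assemble ``Q = -I + R``: negated importance on the diagonal,
    redundancy on the couplings, zero offset."""
    return QuboProblem(
        n=mi.n,
        linear=-mi.importance,
        quadratic=dict(mi.redundancy),
        offset=0.0,
    )


def add_quadratic_constraint(
    q: QuboProblem, spec: SelectionSpec, pen: QuadraticConstraintSpec
) -> QuboProblem:
    """Add ``alpha * (sum_i x_i - k)^2`` (algebraic expansion; fully connects
    the problem graph)."""
    if q.n != spec.n:
        raise DimensionError(f"QUBO has n={q.n} but selection spec has n={spec.n}")
    alpha, k = pen.alpha, spec.k
    quadratic = dict(q.quadratic)
    for i in range(q.n):
        for j in range(i + 1, q.n):
            quadratic[(i, j)] = quadratic.get((i, j), 0.0) + 2.0 * alpha
    return QuboProblem(
        n=q.n,
        linear=q.linear + alpha * (1.0 - 2.0 * k),
        quadratic=quadratic,
        offset=q.offset + alpha * k * k,
    )


def add_linear_penalty(q: QuboProblem, pen: LinearPenaltySpec) -> QuboProblem:
    """Add a uniform diagonal offset; couplings and sparsity are untouched."""
    return replace(q, linear=q.linear + pen.alpha_l, quadratic=dict(q.quadratic))


def energy(q: QuboProblem, mask: np.ndarray) -> float:
    """Evaluate the objective (including offset) on a binary mask."""
    mask = np.asarray(mask)
    if mask.shape != (q.n,):
        raise DimensionError(f"mask must have shape ({q.n},); got {mask.shape}")
    if not np.all(np.isin(mask, (0, 1))):
        raise ValueError("mask entries must be binary")
    mask = mask.astype(float)
    total = float(q.linear @ mask) + q.offset
    for (i, j), value in q.quadratic.items():
        total += value * mask[i] * mask[j]
    return total


def to_ising(q: QuboProblem, spin_domain: str = "pm1") -> IsingProblem:
    """Change of variables to spin space with exact energy correspondence.

    ``"half"`` uses ``x_i = mu_i + 1/2`` with ``mu_i in {-1/2, 1/2}`` (so
    ``J_ij = Q_ij`` and ``h_i = Q_ii + sum_j Q_ij / 2``); ``"pm1"`` uses
    ``x_i = (s_i + 1) / 2``.
    """
    if spin_domain not in IsingProblem._SPINS:
        raise SpecError(f"unknown spin domain {spin_domain!r}")
    h = q.linear.copy() if spin_domain == "half" else q.linear / 2.0
    J: dict[tuple[int, int], float] = {}
    offset = q.offset + float(q.linear.sum()) / 2.0
    for (i, j), value in q.quadratic.items():
        if spin_domain == "half":
            J[(i, j)] = value
            h[i] += value / 2.0
            h[j] += value / 2.0
        else:
            J[(i, j)] = value / 4.0
            h[i] += value / 4.0
            h[j] += value / 4.0
        offset += value / 4.0
    return IsingProblem(n=q.n, h=h, J=J, offset=offset, spin_domain=spin_domain)
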