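"""Classical QUBO solvers and linear-penalty tuning.

Two in-repo solvers stand in for the annealer stack: an exhaustive
enumerator (ground-truth oracle for small ``n``) and multi-restart
single-spin-flip simulated annealing with geometric cooling, which plays the
role of the black-box sampler — of a run's reads, the lowest-energy one is
kept.  A plugin contract (:data:`SOLVERS`) lets an external sampler be
slotted in without touching the pipeline.

``tune_linear_penalty`` adjusts the uniform diagonal offset until the
returned mask has exactly ``k`` ones: bracket by geometric expansion, then
bisect; if no offset yields weight ``k`` within the iteration budget, the
closest solution is greedily repaired and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import CapacityError, TuningError
from .qubo import LinearPenaltySpec, QuboProblem, SelectionSpec, add_linear_penalty
from .sparsify import SubsampleMap

EXHAUSTIVE_CAP = 22

__all__ = [
    "SelectionMask",
    "SolveResult",
    "AnnealParams",
    "solve_exhaustive",
    "solve_sa",
    "solve",
    "tune_linear_penalty",
    "select_features",
    "SOLVERS",
]


@dataclass(frozen=True)
class SelectionMask:
    """A binary selection vector."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int8)
        if bits.ndim != 1 or not np.all(np.isin(bits, (0, 1))):
            raise ValueError("bits must be a 1-D binary vector")
        object.__setattr__(self, "bits", bits)

    @property
    def n(self) -> int:
        return self.bits.shape[0]

    @property
    def hamming_weight(self) -> int:
        return int(self.bits.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


@dataclass(frozen=True)
class SolveResult:
    """Best mask found by a solver run, with provenance."""

    mask: SelectionMask
    energy: float
    solver: str
    n_reads: int
    seed: int | None = None
    read_energies: tuple[float, ...] = ()
    repaired: bool = False
    info: dict = field(default_factory=dict)


@dataclass(frozen=True)
class AnnealParams:
    """Simulated-annealing schedule.

    ``n_reads`` independent restarts, each running ``n_sweeps`` full sweeps
    of single-flip Metropolis under a geometric temperature ladder from
    ``t_hot`` to ``t_cold``.  Unset temperatures are derived from the
    problem's energy scale at solve time.
    """

    n_reads: int = 1000
    n_sweeps: int = 100
    t_hot: float | None = None
    t_cold: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.n_sweeps < 0:
            raise ValueError("n_sweeps must be >= 0")
        if self.t_hot is not None and self.t_cold is not None:
            if not (self.t_hot > self.t_cold > 0):
                raise ValueError("need t_hot > t_cold > 0")


def _lex_bits(indices: np.ndarray, n: int) -> np.ndarray:
    """Decode enumeration indices so that index order == lexicographic mask
    order (bit 0 is the most significant digit)."""
    shifts = n - 1 - np.arange(n)
    return ((indices[:, None] >> shifts[None, :]) & 1).astype(np.int8)


def solve_exhaustive(q: QuboProblem, cap: int = EXHAUSTIVE_CAP) -> SolveResult:
    """Global minimum by enumerating all 2^n masks (chunked).

    Ties are broken toward the lexicographically smallest mask, so the zero
    QUBO yields the empty selection.
    """
    if q.n > cap:
        raise CapacityError(
            f"exhaustive enumeration capped at n={cap}; got n={q.n} "
            "(use the 'sa' solver instead)"
        )
    upper = np.triu(q.dense_upper(), k=1)
    best_energy = np.inf
    best_bits: np.ndarray | None = None
    chunk = 1 << 16
    for start in range(0, 1 << q.n, chunk):
        idx = np.arange(start, min(start + chunk, 1 << q.n), dtype=np.int64)
        bits = _lex_bits(idx, q.n).astype(float)
        energies = bits @ q.linear + np.einsum("bi,ij,bj->b", bits, upper, bits)
        pos = int(np.argmin(energies))
        if energies[pos] < best_energy:
            best_energy = float(energies[pos])
            best_bits = bits[pos].astype(np.int8)
    assert best_bits is not None
    return SolveResult(
        mask=SelectionMask(best_bits),
        energy=best_energy + q.offset,
        solver="exhaustive",
        n_reads=1,
        read_energies=(best_energy + q.offset,),
    )


def _temperature_ladder(
    linear: np.ndarray, coupling: np.ndarray, params: AnnealParams
) -> np.ndarray:
    hot = params.t_hot
    if hot is None:
        # Largest possible single-flip |dE| sets the hot end of the ladder.
        scale = float(np.max(np.abs(linear) + np.abs(coupling).sum(axis=1), initial=0.0))
        hot = scale if scale > 0 else 1.0
    cold = params.t_cold if params.t_cold is not None else max(hot * 1e-3, 1e-12)
    if params.n_sweeps == 0:
        return np.empty(0)
    return np.geomspace(hot, cold, params.n_sweeps)


def solve_sa(q: QuboProblem, params: AnnealParams | None = None) -> SolveResult:
    """Multi-restart simulated annealing; returns the lowest-energy read.

    All restarts are annealed in lockstep (vectorized across reads); the
    per-read best-so-far state is tracked after every sweep.  Fully
    deterministic given ``params.seed``.
    """
    params = params or AnnealParams()
    rng = np.random.default_rng(params.seed)
    linear, coupling = q.dense_symmetric()
    ladder = _temperature_ladder(linear, coupling, params)
    r, n = params.n_reads, q.n

    x = rng.integers(0, 2, size=(r, n)).astype(float)
    fields = x @ coupling + linear  # fields[r, i] = dE of setting x_i from 0
    energies = x @ linear + 0.5 * np.einsum("ri,ri->r", x, x @ coupling)
    best_energy = energies.copy()
    best_x = x.copy()

    for temp in ladder:
        for i in range(n):
            delta = (1.0 - 2.0 * x[:, i]) * fields[:, i]
            accept = rng.random(r) < np.exp(-np.maximum(delta, 0.0) / temp)
            dx = np.where(accept, 1.0 - 2.0 * x[:, i], 0.0)
            x[:, i] += dx
            fields += dx[:, None] * coupling[i][None, :]
            energies += np.where(accept, delta, 0.0)
        improved = energies < best_energy
        if improved.any():
            best_energy[improved] = energies[improved]
            best_x[improved] = x[improved]

    read_energies = best_energy + q.offset
    pos = int(np.argmin(read_energies))
    return SolveResult(
        mask=SelectionMask(best_x[pos].astype(np.int8)),
        energy=float(read_energies[pos]),
        solver="sa",
        n_reads=r,
        seed=params.seed,
        read_energies=tuple(float(e) for e in read_energies),
    )


# Solver plugin registry: any callable (QuboProblem, AnnealParams|None) -> SolveResult.
SOLVERS: dict[str, Callable[..., SolveResult]] = {
    "exhaustive": lambda q, params=None: solve_exhaustive(q),
    "sa": solve_sa,
}


def solve(q: QuboProblem, solver: str = "sa", params: AnnealParams | None = None) -> SolveResult:
    """Dispatch to a registered solver by tag."""
    try:
        fn = SOLVERS[solver]
    except KeyError:
        raise ValueError(f"unknown solver {solver!r}; known: {sorted(SOLVERS)}")
    return fn(q, params)


def _greedy_repair(
    q: QuboProblem, bits: np.ndarray, k: int
) -> np.ndarray:
    """Adjust a mask to Hamming weight k by locally optimal adds/removes
    under the base (pre-penalty) objective; ties toward the smallest index."""
    linear, coupling = q.dense_symmetric()
    bits = bits.astype(float).copy()
    while int(bits.sum()) < k:
        contrib = linear + coupling @ bits
        contrib[bits == 1] = np.inf
        bits[int(np.argmin(contrib))] = 1.0
    while int(bits.sum()) > k:
        contrib = linear + coupling @ bits
        contrib[bits == 0] = -np.inf
        bits[int(np.argmax(contrib))] = 0.0
    return bits.astype(np.int8)


def tune_linear_penalty(
    q: QuboProblem,
    spec: SelectionSpec,
    solver: str = "exhaustive",
    params: AnnealParams | None = None,
    *,
    initial_step: float | None = None,
    max_expansions: int = 40,
    max_bisections: int = 60,
) -> tuple[LinearPenaltySpec, SolveResult]:
    """Tune the uniform diagonal offset so the solution has exactly k ones.

    ``q`` must be the pre-penalty objective.  Starting from offset 0 the
    weight is pushed toward ``k`` by geometric step expansion (the solution's
    Hamming weight is non-increasing in the offset), then bisection once the
    target is straddled.  Each candidate offset triggers a fresh solve with
    identical solver parameters.  If no offset hits ``k`` exactly, the
    closest solution is greedily repaired and the result flagged.
    """
    if q.n != spec.n:
        raise TuningError(f"QUBO has n={q.n} but selection spec has n={spec.n}")

    trajectory: list[tuple[float, int]] = []

    def attempt(alpha: float) -> tuple[int, SolveResult]:
        result = solve(add_linear_penalty(q, LinearPenaltySpec(alpha)), solver, params)
        trajectory.append((alpha, result.mask.hamming_weight))
        return result.mask.hamming_weight, result

    def finish(alpha: float, result: SolveResult, repaired: bool) -> tuple[LinearPenaltySpec, SolveResult]:
        info = dict(result.info)
        info["penalty_trajectory"] = tuple(trajectory)
        info["alpha_l"] = alpha
        return LinearPenaltySpec(alpha), SolveResult(
            mask=result.mask,
            energy=result.energy,
            solver=result.solver,
            n_reads=result.n_reads,
            seed=result.seed,
            read_energies=result.read_energies,
            repaired=repaired,
            info=info,
        )

    weight, result = attempt(0.0)
    if weight == spec.k:
        return finish(0.0, result, repaired=False)

    if initial_step is None:
        scale = float(np.max(np.abs(q.linear), initial=0.0))
        if scale == 0.0 and q.quadratic:
            scale = max(abs(v) for v in q.quadratic.values())
        initial_step = scale / 10.0 if scale > 0 else 1.0

    # Bracket: push alpha away from 0 until the weight crosses k.
    # Weight is non-increasing in alpha, so too-many-selected needs alpha > 0.
    sign = 1.0 if weight > spec.k else -1.0
    lo_alpha, lo_weight = 0.0, weight  # side where weight is on the alpha=0 side of k
    hi_alpha: float | None = None
    hi_result: SolveResult | None = None
    step = initial_step
    for _ in range(max_expansions):
        alpha = lo_alpha + sign * step
        w, res = attempt(alpha)
        if w == spec.k:
            return finish(alpha, res, repaired=False)
        crossed = (w < spec.k) if sign > 0 else (w > spec.k)
        if crossed:
            hi_alpha, hi_result = alpha, res
            break
        lo_alpha, lo_weight = alpha, w
        step *= 2.0

    candidates: list[tuple[int, float, SolveResult]] = [
        (abs(w - spec.k), a, r)
        for (a, w), r in zip([(0.0, weight)], [result])
    ]
    if hi_alpha is None:
        raise TuningError(
            "penalty bracketing exhausted without crossing the target weight; "
            f"trajectory={trajectory}"
        )
    candidates.append((abs(hi_result.mask.hamming_weight - spec.k), hi_alpha, hi_result))

    a_lo, a_hi = lo_alpha, hi_alpha
    for _ in range(max_bisections):
        if abs(a_hi - a_lo) <= 1e-12 * max(1.0, abs(a_hi)):
            break  # interval collapsed onto a weight discontinuity
        mid = (a_lo + a_hi) / 2.0
        w, res = attempt(mid)
        if w == spec.k:
            return finish(mid, res, repaired=False)
        candidates.append((abs(w - spec.k), mid, res))
        on_lo_side = (w > spec.k) if sign > 0 else (w < spec.k)
        if on_lo_side:
            a_lo = mid
        else:
            a_hi = mid

    # No offset produced weight k: repair the closest candidate.
    _, alpha, res = min(candidates, key=lambda c: (c[0], abs(c[1])))
    repaired_bits = _greedy_repair(q, res.mask.bits, spec.k)
    penalized = add_linear_penalty(q, LinearPenaltySpec(alpha))
    repaired_mask = SelectionMask(repaired_bits)
    return finish(
        alpha,
        SolveResult(
            mask=repaired_mask,
            energy=penalized.energy(repaired_bits),
            solver=res.solver,
            n_reads=res.n_reads,
            seed=res.seed,
            read_energies=res.read_energies,
        ),
        repaired=True,
    )


def select_features(
    result: SolveResult | SelectionMask,
    coord_map: Sequence[tuple[int, int]],
    subsample_map: SubsampleMap | None = None,
) -> list[tuple[int, int]]:
    """Map a solver mask back to original pixel coordinates (row-major order).

    With a :class:`SubsampleMap`, mask position ``j`` refers to original flat
    index ``kept_indices[j]``; ``coord_map`` is then indexed in the original
    (pre-subsampling) feature space.
    """
    mask = result.mask if isinstance(result, SolveResult) else result
    if subsample_map is not None:
        if mask.n != subsample_map.n_reduced:
            raise ValueError("mask length does not match the subsample map")
        flat = [subsample_map.kept_indices[j] for j in mask.indices()]
    else:
        if mask.n != len(coord_map):
            raise ValueError("mask length does not match the coordinate map")
        flat = list(mask.indices())
    return sorted(tuple(coord_map[i]) for i in flat)
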