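"""End-to-end experiment orchestration.

Wires the stages together — data -> quantile binning -> MI -> QUBO ->
(optional) sparsification -> solve -> pixel mask -> decoder training ->
test-set MSE — with structured config, per-stage logging, and fully seeded
reproducibility.  Repeat ``r`` of any stochastic step uses a seed derived by
hashing ``(master_seed, stage, r)``; there is no hidden RNG state.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .baselines import SparsePcaCoder, select_by_coefficients, select_grid, select_random
from .data import FlatDataset, ImageDataset, SyntheticSpec, flatten, generate_synthetic, load_npz_dataset
from .decoder import (
    Autoencoder,
    DecoderConfig,
    build_decoder,
    evaluate_mse_on_codes,
    mask_to_codes,
    train_on_codes,
)
from .exceptions import CapacityError, ConfigError
from .mi import discretize, estimate_importance, estimate_mi_matrices, estimate_redundancy
from .qubo import (
    QuadraticConstraintSpec,
    QuboProblem,
    SelectionSpec,
    add_quadratic_constraint,
    build_mi_qubo,
)
from .solvers import (
    EXHAUSTIVE_CAP,
    AnnealParams,
    SelectionMask,
    SolveResult,
    _greedy_repair,
    select_features,
    solve,
    tune_linear_penalty,
)
from .sparsify import restrict_dataset, subsample_by_importance, threshold_couplings

logger = logging.getLogger("qubofs")

BENCHMARK_METHODS = (
    "random",
    "sampled",
    "lasso",
    "qubo_full",
    "qubo_sparsified",
    "autoencoder",
    "spca",
)

__all__ = [
    "ExperimentConfig",
    "EvalReport",
    "derive_seed",
    "run_full_qubo_experiment",
    "run_sparsified_experiment",
    "run_benchmark",
    "select_full_qubo_mask",
    "select_sparsified_mask",
]


def derive_seed(master_seed: int, *parts) -> int:
    """Stable 32-bit seed derived from the master seed and a stage label."""
    digest = hashlib.sha256(repr((master_seed,) + parts).encode()).digest()
    return int.from_bytes(digest[:4], "little")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    # dataset: either an NPZ archive path or a synthetic recipe
    npz_path: str | None = None
    dataset_name: str = "synthetic"
    synthetic: SyntheticSpec | None = None
    synthetic_test_samples: int = 500

    n_bins: int = 20
    k: int = 25
    constraint: str = "linear"  # "linear" | "quadratic"
    alpha: float | None = None  # quadratic penalty weight; default 2x the MI scale
    sparsify: bool = True
    block: tuple[int, int] = (2, 2)
    n_couplings: int = 2000
    solver: str = "sa"
    anneal: AnnealParams = field(default_factory=AnnealParams)

    decoder_channels: tuple[int, int] = (32, 16)
    decoder_epochs: int = 20
    decoder_learning_rate: float = 0.001
    decoder_batch_size: int = 128

    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.npz_path is None) == (self.synthetic is None):
            raise ConfigError("provide exactly one of npz_path or synthetic")
        if self.constraint not in ("linear", "quadratic"):
            raise ConfigError(f"unknown constraint mode {self.constraint!r}")
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")
        object.__setattr__(self, "block", tuple(self.block))
        object.__setattr__(self, "decoder_channels", tuple(self.decoder_channels))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in payload and payload["synthetic"] is not None:
            syn = payload["synthetic"]
            for key in ("informative_pixels",):
                if key in syn:
                    syn[key] = tuple(map(tuple, syn[key]))
            if "redundancy_groups" in syn:
                syn["redundancy_groups"] = tuple(
                    tuple(map(tuple, g)) for g in syn["redundancy_groups"]
                )
            payload["synthetic"] = SyntheticSpec(**syn)
        if "anneal" in payload and payload["anneal"] is not None:
            payload["anneal"] = AnnealParams(**payload["anneal"])
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]

    def decoder_config(self, side: int, seed: int) -> DecoderConfig:
        return DecoderConfig(
            k=self.k,
            side=side,
            c1=self.decoder_channels[0],
            c2=self.decoder_channels[1],
            learning_rate=self.decoder_learning_rate,
            epochs=self.decoder_epochs,
            batch_size=self.decoder_batch_size,
            seed=seed,
        )


@dataclass(frozen=True)
class EvalReport:
    """Per-method reconstruction summary (mean +/- std of test MSE over
    repeats) plus provenance metadata."""

    table: pd.DataFrame
    metadata: dict

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(Path(path), index=False)

    @staticmethod
    def from_rows(rows: list[dict], metadata: dict) -> "EvalReport":
        return EvalReport(table=pd.DataFrame(rows), metadata=metadata)


# ---------------------------------------------------------------------------
# data access


def load_train_test(cfg: ExperimentConfig) -> tuple[ImageDataset, ImageDataset]:
    if cfg.npz_path is not None:
        return (
            load_npz_dataset(cfg.npz_path, "train", name=cfg.dataset_name),
            load_npz_dataset(cfg.npz_path, "test", name=cfg.dataset_name),
        )
    assert cfg.synthetic is not None
    train = generate_synthetic(cfg.synthetic, split="train")
    test_spec = replace(
        cfg.synthetic,
        n_samples=cfg.synthetic_test_samples,
        seed=derive_seed(cfg.synthetic.seed, "test-split"),
    )
    test = generate_synthetic(test_spec, split="test")
    return train, test


# ---------------------------------------------------------------------------
# selection stages


def _coords_to_grid_mask(coords: Iterable[tuple[int, int]], shape: tuple[int, int]) -> SelectionMask:
    h, w = shape
    bits = np.zeros(h * w, dtype=np.int8)
    for r, c in coords:
        bits[r * w + c] = 1
    return SelectionMask(bits)


def _base_scale(base: QuboProblem) -> float:
    """Magnitude of the largest MI coefficient; sets penalty and SA scales."""
    scale = float(np.max(np.abs(base.linear), initial=0.0))
    if base.quadratic:
        scale = max(scale, max(abs(v) for v in base.quadratic.values()))
    return scale if scale > 0 else 1.0


def _anneal_params(cfg: ExperimentConfig, base: QuboProblem, seed: int | None) -> AnnealParams:
    """Fill in the SA seed and, if unset, temperatures matched to the
    pre-constraint coefficient scale (a generic ladder derived from the
    penalized problem would be far too hot to resolve MI-scale differences
    between feasible masks)."""
    params = replace(cfg.anneal, seed=seed if seed is not None else cfg.anneal.seed)
    if params.t_hot is None and cfg.solver == "sa":
        scale = _base_scale(base)
        params = replace(params, t_hot=4.0 * scale, t_cold=scale / 300.0)
    return params


def select_full_qubo_mask(
    train_fd: FlatDataset, cfg: ExperimentConfig, seed: int | None = None
) -> tuple[SelectionMask, dict]:
    """MI-QUBO selection on the full feature space; the cardinality
    constraint follows ``cfg.constraint`` (quadratic penalty by default for
    this dense path).  Returns a full-grid pixel mask."""
    t0 = time.perf_counter()
    dd = discretize(train_fd, cfg.n_bins)
    mi = estimate_mi_matrices(dd)
    base = build_mi_qubo(mi)
    spec = SelectionSpec(k=cfg.k, n=base.n)
    solver = cfg.solver
    if solver == "exhaustive" and base.n > EXHAUSTIVE_CAP:
        raise CapacityError(
            f"n={base.n} exceeds the exhaustive cap ({EXHAUSTIVE_CAP}); "
            "configure solver='sa'"
        )
    params = _anneal_params(cfg, base, seed)
    alpha: float | None = None
    if cfg.constraint == "quadratic":
        alpha = cfg.alpha if cfg.alpha is not None else 2.0 * _base_scale(base)
        constrained = add_quadratic_constraint(base, spec, QuadraticConstraintSpec(alpha))
        result = solve(constrained, solver, params)
        bits = result.mask.bits
        repaired = False
        if result.mask.hamming_weight != cfg.k:  # soft penalty: repair misses
            bits = _greedy_repair(base, bits, cfg.k)
            repaired = True
        n_couplings = constrained.n_couplings
    else:
        pen, result = tune_linear_penalty(base, spec, solver=solver, params=params)
        bits = result.mask.bits
        repaired = result.repaired
        alpha = pen.alpha_l
        n_couplings = base.n_couplings
    coords = select_features(SelectionMask(bits), train_fd.coord_map)
    mask = _coords_to_grid_mask(coords, train_fd.image_shape)
    info = {
        "n": base.n,
        "n_couplings": n_couplings,
        "alpha": alpha,
        "energy": result.energy,
        "repaired": repaired,
        "coords": coords,
        "seconds": time.perf_counter() - t0,
    }
    logger.info("full-QUBO selection: %s", {k: v for k, v in info.items() if k != "coords"})
    return mask, info


def select_sparsified_mask(
    train_fd: FlatDataset, cfg: ExperimentConfig, seed: int | None = None
) -> tuple[SelectionMask, dict]:
    """Hardware-style selection: block subsampling by importance, coupling
    thresholding, then linear-penalty tuning; returns a full-grid mask."""
    t0 = time.perf_counter()
    dd = discretize(train_fd, cfg.n_bins)
    importance = estimate_importance(dd)
    sm = subsample_by_importance(importance, train_fd.image_shape, cfg.block)
    kept = list(sm.kept_indices)
    dd_reduced = dd.restrict(kept)
    n = len(kept)
    redundancy = estimate_redundancy(dd_reduced)
    base = QuboProblem(n=n, linear=-importance[kept], quadratic=redundancy)
    sparse = threshold_couplings(base, cfg.n_couplings)
    params = _anneal_params(cfg, sparse, seed)
    pen, result = tune_linear_penalty(
        sparse, SelectionSpec(k=cfg.k, n=n), solver=cfg.solver, params=params
    )
    coords = select_features(result, train_fd.coord_map, subsample_map=sm)
    mask = _coords_to_grid_mask(coords, train_fd.image_shape)
    info = {
        "n": n,
        "n_couplings": sparse.n_couplings,
        "alpha_l": pen.alpha_l,
        "energy": result.energy,
        "repaired": result.repaired,
        "penalty_trajectory": result.info.get("penalty_trajectory"),
        "subsample_map": sm,
        "coords": coords,
        "seconds": time.perf_counter() - t0,
    }
    logger.info(
        "sparsified selection: n=%d couplings=%d alpha_l=%.4g repaired=%s (%.1fs)",
        n, sparse.n_couplings, pen.alpha_l, result.repaired, info["seconds"],
    )
    return mask, info


# ---------------------------------------------------------------------------
# reconstruction evaluation


def _evaluate_mask(
    mask: SelectionMask,
    train: ImageDataset,
    test: ImageDataset,
    cfg: ExperimentConfig,
    seed: int,
) -> float:
    dec_cfg = cfg.decoder_config(train.side, seed)
    dec = build_decoder(dec_cfg)
    train_on_codes(dec, mask_to_codes(train.images, mask), train.images, dec_cfg)
    return evaluate_mse_on_codes(dec, mask_to_codes(test.images, mask), test.images)


def _repeat_seeds(cfg: ExperimentConfig, stage: str) -> list[int]:
    return [derive_seed(cfg.seed, stage, r) for r in range(cfg.repeats)]


def _summary_row(method: str, dataset: str, cfg: ExperimentConfig, mses: Sequence[float]) -> dict:
    mses = np.asarray(mses, dtype=float)
    return {
        "method": method,
        "dataset": dataset,
        "k": cfg.k,
        "repeats": len(mses),
        "mean_mse": float(mses.mean()),
        "std_mse": float(mses.std(ddof=1)) if len(mses) > 1 else 0.0,
    }


def _metadata(cfg: ExperimentConfig) -> dict:
    return {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
    }


def run_full_qubo_experiment(cfg: ExperimentConfig) -> EvalReport:
    """Dense-QUBO (quadratic constraint) selection plus reconstruction."""
    train, test = load_train_test(cfg)
    train_fd = flatten(train)
    mses = []
    for r, seed in enumerate(_repeat_seeds(cfg, "qubo_full")):
        mask, _ = select_full_qubo_mask(train_fd, cfg, seed=seed)
        mses.append(_evaluate_mask(mask, train, test, cfg, seed))
        logger.info("qubo_full repeat %d: test MSE %.5f", r, mses[-1])
    return EvalReport.from_rows(
        [_summary_row("qubo_full", train.name, cfg, mses)], _metadata(cfg)
    )


def run_sparsified_experiment(cfg: ExperimentConfig) -> EvalReport:
    """Subsampled + thresholded + linear-penalty selection plus reconstruction."""
    train, test = load_train_test(cfg)
    train_fd = flatten(train)
    mses = []
    for r, seed in enumerate(_repeat_seeds(cfg, "qubo_sparsified")):
        mask, _ = select_sparsified_mask(train_fd, cfg, seed=seed)
        mses.append(_evaluate_mask(mask, train, test, cfg, seed))
        logger.info("qubo_sparsified repeat %d: test MSE %.5f", r, mses[-1])
    return EvalReport.from_rows(
        [_summary_row("qubo_sparsified", train.name, cfg, mses)], _metadata(cfg)
    )


def run_benchmark(cfg: ExperimentConfig, methods: Sequence[str]) -> EvalReport:
    """One report row per selection/compression method, mean +/- std over
    ``cfg.repeats`` reconstruction repeats."""
    deduped: list[str] = []
    for method in methods:
        if method in deduped:
            logger.warning("duplicate benchmark method %r ignored", method)
            continue
        if method not in BENCHMARK_METHODS:
            raise ConfigError(
                f"unknown benchmark method {method!r}; known: {BENCHMARK_METHODS}"
            )
        deduped.append(method)

    train, test = load_train_test(cfg)
    train_fd = flatten(train)
    n = train_fd.n_features
    rows = []
    for method in deduped:
        seeds = _repeat_seeds(cfg, method)
        mses: list[float] = []
        for r, seed in enumerate(seeds):
            if method == "random":
                mask = select_random(n, cfg.k, seed=seed)
                mses.append(_evaluate_mask(mask, train, test, cfg, seed))
            elif method == "sampled":
                mask = select_grid(train_fd.image_shape, cfg.k)
                mses.append(_evaluate_mask(mask, train, test, cfg, seed))
            elif method == "lasso":
                mask = select_by_coefficients(train_fd, cfg.k)
                mses.append(_evaluate_mask(mask, train, test, cfg, seed))
            elif method == "qubo_full":
                mask, _ = select_full_qubo_mask(train_fd, cfg, seed=seed)
                mses.append(_evaluate_mask(mask, train, test, cfg, seed))
            elif method == "qubo_sparsified":
                mask, _ = select_sparsified_mask(train_fd, cfg, seed=seed)
                mses.append(_evaluate_mask(mask, train, test, cfg, seed))
            elif method == "spca":
                coder = SparsePcaCoder(cfg.k, seed=seed).fit(train_fd.features)
                dec_cfg = cfg.decoder_config(train.side, seed)
                dec = build_decoder(dec_cfg)
                train_on_codes(dec, coder.encode(train_fd.features), train.images, dec_cfg)
                test_codes = coder.encode(test.images.reshape(test.n_samples, -1))
                mses.append(evaluate_mse_on_codes(dec, test_codes, test.images))
            elif method == "autoencoder":
                dec_cfg = cfg.decoder_config(train.side, seed)
                ae = Autoencoder(n, dec_cfg)
                ae.fit(train.images)
                mses.append(ae.mse(test.images))
            logger.info("%s repeat %d: test MSE %.5f", method, r, mses[-1])
        rows.append(_summary_row(method, train.name, cfg, mses))
    return EvalReport.from_rows(rows, _metadata(cfg))
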