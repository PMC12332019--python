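import numpy as np
import pytest

import qubofs as qf


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def planted_spec_16(seed: int, n_samples: int = 1500) -> qf.SyntheticSpec:
    """Calibrated 16x16 planted benchmark: 25 informative pixels with
    per-pixel binary class splits (8 classes), 8 redundancy groups of 8."""
    layout_rng = np.random.default_rng(12345)
    coords = [(r, c) for r in range(16) for c in range(16)]
    picks = layout_rng.choice(len(coords), size=25 + 8 * 8, replace=False)
    informative = tuple(coords[i] for i in picks[:25])
    groups = tuple(
        tuple(coords[i] for i in picks[25 + 8 * g: 25 + 8 * (g + 1)])
        for g in range(8)
    )
    return qf.SyntheticSpec(
        n_samples=n_samples,
        height=16,
        width=16,
        n_classes=8,
        informative_pixels=informative,
        redundancy_groups=groups,
        noise_sd=0.05,
        group_class_shift=0.3,
        group_latent_sd=0.3,
        class_assignment="split",
        structure_seed=99,
        seed=seed,
    )


def brute_force_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Independent MI oracle: enumerate the full contingency table of two
    discrete sequences and sum p * log(p / (px * py)) directly."""
    from collections import Counter
    from math import log

    n = len(x)
    joint = Counter(zip(x.tolist(), y.tolist()))
    px = Counter(x.tolist())
    py = Counter(y.tolist())
    total = 0.0
    for (a, b), count in joint.items():
        p = count / n
        total += p * log(p / ((px[a] / n) * (py[b] / n)))
    return total


def random_qubo(n: int, rng: np.random.Generator, density: float = 0.6) -> qf.QuboProblem:
    """Random dense-ish QUBO instance for solver tests."""
    linear = rng.normal(0.0, 1.0, size=n)
    quadratic = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                quadratic[(i, j)] = float(rng.normal(0.0, 1.0))
    return qf.QuboProblem(n=n, linear=linear, quadratic=quadratic,
                          offset=float(rng.normal()))


def random_mask(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 2, size=n).astype(np.int8)


@pytest.fixture
def tiny_dataset():
    """Deterministic 6x6 dataset with 3 informative pixels and one group."""
    spec = qf.SyntheticSpec(
        n_samples=600,
        height=6,
        width=6,
        n_classes=2,
        informative_pixels=((0, 0), (1, 1), (2, 2)),
        redundancy_groups=(((3, 3), (3, 4), (4, 3)),),
        seed=11,
    )
    return qf.generate_synthetic(spec)
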