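import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qubofs as qf
from qubofs.mi import ProbabilityTables, _mi_from_counts

from conftest import brute_force_mi


def make_flat(features: np.ndarray, labels: np.ndarray) -> qf.FlatDataset:
    n = features.shape[1]
    return qf.FlatDataset(
        features=features,
        labels=labels,
        coord_map=tuple((0, j) for j in range(n)),
        image_shape=(1, n),
    )


class TestDiscretize:
    def test_1_to_100_gives_20_equal_bins(self):
        values = np.arange(1, 101, dtype=float)
        fd = make_flat(values[:, None], np.zeros(100, dtype=int))
        dd = qf.discretize(fd, 20)
        counts = np.bincount(dd.bins[:, 0])
        assert len(counts) == 20
        assert (counts == 5).all()

    def test_constant_feature_single_bin(self):
        fd = make_flat(np.full((50, 1), 0.7), np.zeros(50, dtype=int))
        dd = qf.discretize(fd, 20)
        assert dd.effective_bins == (1,)
        assert (dd.bins == 0).all()
        assert qf.estimate_importance(dd)[0] == 0.0

    def test_default_bin_count_is_20(self):
        from qubofs.mi import DEFAULT_N_BINS

        assert DEFAULT_N_BINS == 20

    def test_bin_index_counts_edges_strictly_below(self, rng):
        values = rng.normal(size=200)
        fd = make_flat(values[:, None], np.zeros(200, dtype=int))
        dd = qf.discretize(fd, 10)
        edges = dd.bin_edges[0]
        for value, bin_idx in zip(values, dd.bins[:, 0]):
            assert bin_idx == int((edges < value).sum())

    def test_bins_within_effective_range(self, rng):
        features = rng.integers(0, 4, size=(100, 3)).astype(float)
        fd = make_flat(features, np.zeros(100, dtype=int))
        dd = qf.discretize(fd, 20)
        for j in range(3):
            assert dd.bins[:, j].max() < dd.effective_bins[j] <= 20


class TestProbabilityTables:
    def test_tables_normalized_and_consistent(self, rng):
        features = rng.normal(size=(300, 4))
        labels = rng.integers(0, 3, size=300)
        tables = ProbabilityTables(qf.discretize(make_flat(features, labels), 8))
        for i in range(4):
            fy = tables.joint_feature_label(i)
            assert fy.min() >= 0
            assert abs(fy.sum() - 1.0) < 1e-12
            np.testing.assert_allclose(fy.sum(axis=1), tables.marginal_feature(i))
            np.testing.assert_allclose(fy.sum(axis=0), tables.marginal_label())
        ff = tables.joint_feature_pair(0, 1)
        assert abs(ff.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(ff.sum(axis=1), tables.marginal_feature(0))


class TestImportance:
    def test_feature_identical_to_balanced_binary_label(self):
        labels = np.array([0, 1] * 50)
        fd = make_flat(labels[:, None].astype(float), labels)
        mi = qf.estimate_importance(qf.discretize(fd, 20))
        assert mi[0] == pytest.approx(math.log(2), abs=1e-12)

    def test_independent_feature_below_dependent_one(self, rng):
        labels = np.array([0, 1] * 100)
        dependent = labels.astype(float)
        independent = rng.permutation(dependent)
        fd = make_flat(np.column_stack([dependent, independent]), labels)
        mi = qf.estimate_importance(qf.discretize(fd, 20))
        assert mi[1] < mi[0]
        assert mi[1] < 0.05

    def test_eight_sample_worked_table(self):
        # counts: (b=0,y=0)=3, (0,1)=1, (1,0)=1, (1,1)=3
        features = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        labels = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        mi = qf.estimate_importance(qf.discretize(make_flat(features[:, None], labels), 2))
        expected = sum(
            p * math.log(p / (pb * py))
            for p, pb, py in [
                (3 / 8, 1 / 2, 1 / 2),
                (1 / 8, 1 / 2, 1 / 2),
                (1 / 8, 1 / 2, 1 / 2),
                (3 / 8, 1 / 2, 1 / 2),
            ]
        )
        assert mi[0] == pytest.approx(expected, abs=1e-12)

    def test_empty_dataset_rejected(self):
        dd = qf.DiscretizedDataset(
            bins=np.empty((0, 1), dtype=int),
            bin_edges=(np.array([]),),
            labels=np.empty(0, dtype=int),
        )
        with pytest.raises(ValueError):
            qf.estimate_importance(dd)


class TestRedundancy:
    def test_identical_features_share_entropy(self):
        values = np.tile(np.arange(4, dtype=float), 25)
        fd = make_flat(np.column_stack([values, values]), np.zeros(100, dtype=int))
        red = qf.estimate_redundancy(qf.discretize(fd, 4))
        assert red[(0, 1)] == pytest.approx(math.log(4), abs=1e-12)

    def test_independent_pair_near_zero(self, rng):
        a = np.tile(np.arange(4, dtype=float), 100)
        b = rng.permutation(a)
        fd = make_flat(np.column_stack([a, b]), np.zeros(400, dtype=int))
        red = qf.estimate_redundancy(qf.discretize(fd, 4))
        assert red[(0, 1)] < 0.05

    def test_symmetric_under_column_swap(self, rng):
        features = rng.normal(size=(150, 2))
        fd = make_flat(features, np.zeros(150, dtype=int))
        swapped = make_flat(features[:, ::-1], np.zeros(150, dtype=int))
        forward = qf.estimate_redundancy(qf.discretize(fd, 6))[(0, 1)]
        backward = qf.estimate_redundancy(qf.discretize(swapped, 6))[(0, 1)]
        assert forward == pytest.approx(backward, abs=1e-12)

    def test_pair_validation(self, rng):
        fd = make_flat(rng.normal(size=(20, 2)), np.zeros(20, dtype=int))
        dd = qf.discretize(fd, 4)
        with pytest.raises(Exception):
            qf.estimate_redundancy(dd, [(1, 0)])
        with pytest.raises(Exception):
            qf.estimate_redundancy(dd, [(0, 5)])

    def test_default_computes_all_pairs(self, rng):
        fd = make_flat(rng.normal(size=(30, 4)), np.zeros(30, dtype=int))
        red = qf.estimate_redundancy(qf.discretize(fd, 4))
        assert set(red) == {(i, j) for i in range(4) for j in range(i + 1, 4)}


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_contingency(self, seed):
        rng = np.random.default_rng(seed)
        n_features = int(rng.integers(2, 6))
        features = rng.integers(0, 4, size=(80, n_features)).astype(float)
        labels = rng.integers(0, 3, size=80)
        dd = qf.discretize(make_flat(features, labels), 4)
        importance = qf.estimate_importance(dd)
        for j in range(n_features):
            oracle = brute_force_mi(dd.bins[:, j], labels)
            assert importance[j] == pytest.approx(oracle, abs=1e-10)
        red = qf.estimate_redundancy(dd)
        for (i, j), value in red.items():
            oracle = brute_force_mi(dd.bins[:, i], dd.bins[:, j])
            assert value == pytest.approx(oracle, abs=1e-10)


class TestProperties:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_mi_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 6, size=(4, 3))
        if counts.sum() == 0:
            counts[0, 0] = 1
        assert _mi_from_counts(counts) >= 0.0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_merging_bins_never_increases_label_mi(self, seed):
        # data-processing inequality on the empirical distribution
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 8, size=(5, 3))
        if counts.sum() == 0:
            counts[0, 0] = 1
        merged = np.vstack([counts[0] + counts[1], counts[2:]])
        assert _mi_from_counts(merged) <= _mi_from_counts(counts) + 1e-12


class TestSerialization:
    def test_mi_cache_round_trip(self, tmp_path, rng):
        mi = qf.MIMatrices(
            importance=rng.uniform(size=6),
            redundancy={(0, 1): 0.5, (2, 5): 0.25},
        )
        path = tmp_path / "mi.npz"
        from qubofs.mi import load_mi, save_mi

        save_mi(mi, path)
        loaded = load_mi(path)
        np.testing.assert_allclose(loaded.importance, mi.importance)
        assert loaded.redundancy == mi.redundancy

    def test_redundancy_matrix_symmetric(self):
        mi = qf.MIMatrices(importance=np.zeros(3), redundancy={(0, 2): 0.4})
        mat = mi.redundancy_matrix()
        np.testing.assert_array_equal(mat, mat.T)
        assert mat[0, 2] == 0.4
        assert np.all(np.diag(mat) == 0)
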