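import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qubofs as qf
from qubofs.exceptions import SpecError

from conftest import random_qubo


def all_masks(n: int):
    return (np.array(bits, dtype=np.int8) for bits in itertools.product((0, 1), repeat=n))


class TestBuildMiQubo:
    def test_direct_substitution(self):
        mi = qf.MIMatrices(importance=np.array([0.5, 0.3]), redundancy={(0, 1): 0.1})
        q = qf.build_mi_qubo(mi)
        np.testing.assert_allclose(q.linear, [-0.5, -0.3])
        assert q.quadratic == {(0, 1): 0.1}
        assert q.offset == 0.0
        assert q.energy(np.array([1, 1])) == pytest.approx(-0.7)
        assert q.energy(np.array([1, 0])) == pytest.approx(-0.5)

    def test_zero_mi_gives_zero_qubo(self):
        q = qf.build_mi_qubo(qf.MIMatrices(importance=np.zeros(4)))
        for mask in all_masks(4):
            assert q.energy(mask) == 0.0


class TestQuadraticConstraint:
    def test_closed_form_in_hamming_weight(self):
        base = qf.QuboProblem(n=3, linear=np.zeros(3))
        con = qf.add_quadratic_constraint(
            base, qf.SelectionSpec(k=1, n=3), qf.QuadraticConstraintSpec(1.0)
        )
        by_weight = {}
        for mask in all_masks(3):
            by_weight.setdefault(int(mask.sum()), set()).add(round(con.energy(mask), 9))
        assert by_weight == {0: {1.0}, 1: {0.0}, 2: {1.0}, 3: {4.0}}

    @pytest.mark.parametrize("n,k,alpha", [(6, 2, 1.7), (8, 5, 0.3)])
    def test_penalty_vanishes_exactly_at_k(self, n, k, alpha):
        base = qf.QuboProblem(n=n, linear=np.zeros(n))
        con = qf.add_quadratic_constraint(
            base, qf.SelectionSpec(k=k, n=n), qf.QuadraticConstraintSpec(alpha)
        )
        for mask in all_masks(n):
            h = int(mask.sum())
            assert con.energy(mask) == pytest.approx(alpha * (h - k) ** 2, abs=1e-9)

    def test_fully_connected_afterwards(self, rng):
        base = random_qubo(5, rng, density=0.2)
        con = qf.add_quadratic_constraint(
            base, qf.SelectionSpec(k=2, n=5), qf.QuadraticConstraintSpec(1.0)
        )
        assert set(con.quadratic) == {(i, j) for i in range(5) for j in range(i + 1, 5)}

    def test_alpha_must_be_positive(self):
        with pytest.raises(SpecError):
            qf.QuadraticConstraintSpec(0.0)


class TestLinearPenalty:
    def test_zero_offset_is_identity(self, rng):
        q = random_qubo(5, rng)
        shifted = qf.add_linear_penalty(q, qf.LinearPenaltySpec(0.0))
        np.testing.assert_array_equal(shifted.linear, q.linear)
        assert shifted.quadratic == q.quadratic
        assert shifted.offset == q.offset

    def test_large_offset_empties_the_optimum(self, rng):
        for _ in range(5):
            q = random_qubo(8, rng)
            # all linear terms > -10 after clipping
            q = qf.QuboProblem(
                n=8, linear=np.clip(q.linear, -9.0, None), quadratic=q.quadratic
            )
            shifted = qf.add_linear_penalty(q, qf.LinearPenaltySpec(10.0 + 8))
            best = min(all_masks(8), key=lambda m: shifted.energy(m))
            assert best.sum() == 0

    def test_sparsity_preserved(self, rng):
        q = random_qubo(6, rng, density=0.3)
        shifted = qf.add_linear_penalty(q, qf.LinearPenaltySpec(2.5))
        assert shifted.n_couplings == q.n_couplings
        assert set(shifted.quadratic) == set(q.quadratic)


class TestEnergy:
    def test_empty_mask_returns_offset(self, rng):
        q = random_qubo(4, rng)
        assert q.energy(np.zeros(4, dtype=int)) == pytest.approx(q.offset)

    def test_full_mask_sums_all_coefficients(self):
        q = qf.QuboProblem(n=2, linear=np.array([1.0, 1.0]), quadratic={(0, 1): 1.0})
        assert q.energy(np.array([1, 1])) == 3.0

    def test_matches_dense_matrix_oracle(self, rng):
        for _ in range(10):
            q = random_qubo(8, rng)
            dense = q.dense_upper()
            mask = rng.integers(0, 2, size=8).astype(float)
            oracle = float(mask @ dense @ mask) + q.offset
            assert q.energy(mask.astype(int)) == pytest.approx(oracle, abs=1e-12)

    def test_non_binary_rejected(self, rng):
        q = random_qubo(3, rng)
        with pytest.raises(ValueError):
            q.energy(np.array([0, 2, 1]))


class TestIsingConversion:
    def test_single_variable_half_domain(self):
        c = 1.7
        q = qf.QuboProblem(n=1, linear=np.array([c]))
        ising = qf.to_ising(q, "half")
        np.testing.assert_allclose(ising.h, [c])
        assert ising.offset == pytest.approx(c / 2)
        assert ising.energy(np.array([-0.5])) == pytest.approx(0.0)
        assert ising.energy(np.array([0.5])) == pytest.approx(c)

    def test_two_variable_worked_example(self):
        q = qf.QuboProblem(
            n=2, linear=np.array([-0.5, -0.3]), quadratic={(0, 1): 0.1}
        )
        for domain in ("half", "pm1"):
            ising = qf.to_ising(q, domain)
            for mask in all_masks(2):
                assert ising.energy(ising.spins_from_mask(mask)) == pytest.approx(
                    q.energy(mask), abs=1e-12
                )

    def test_zero_qubo_maps_to_zero_ising(self):
        ising = qf.to_ising(qf.QuboProblem(n=3, linear=np.zeros(3)))
        np.testing.assert_array_equal(ising.h, np.zeros(3))
        assert ising.J == {}
        assert ising.offset == 0.0

    @pytest.mark.parametrize("domain", ["half", "pm1"])
    @pytest.mark.parametrize("seed", range(4))
    def test_exhaustive_energy_equivalence(self, domain, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        q = random_qubo(n, rng)
        ising = qf.to_ising(q, domain)
        for mask in all_masks(n):
            assert ising.energy(ising.spins_from_mask(mask)) == pytest.approx(
                q.energy(mask), abs=1e-9
            )

    def test_unknown_domain_rejected(self, rng):
        with pytest.raises(SpecError):
            qf.to_ising(random_qubo(2, rng), "pm2")


class TestAssembly:
    def test_build_order_does_not_matter(self, rng):
        mi = qf.MIMatrices(
            importance=rng.uniform(size=5),
            redundancy={(i, j): float(rng.uniform()) for i in range(5) for j in range(i + 1, 5)},
        )
        spec = qf.SelectionSpec(k=2, n=5)
        pen_q = qf.QuadraticConstraintSpec(0.7)
        pen_l = qf.LinearPenaltySpec(0.3)
        a = qf.add_linear_penalty(
            qf.add_quadratic_constraint(qf.build_mi_qubo(mi), spec, pen_q), pen_l
        )
        b = qf.add_quadratic_constraint(
            qf.add_linear_penalty(qf.build_mi_qubo(mi), pen_l), spec, pen_q
        )
        np.testing.assert_allclose(a.linear, b.linear)
        assert a.quadratic.keys() == b.quadratic.keys()
        for key in a.quadratic:
            assert a.quadratic[key] == pytest.approx(b.quadratic[key])
        assert a.offset == pytest.approx(b.offset)


class TestSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        q = random_qubo(6, rng)
        path = tmp_path / "qubo.json"
        q.to_json(path)
        loaded = qf.QuboProblem.from_json(path)
        np.testing.assert_allclose(loaded.linear, q.linear)
        assert loaded.quadratic == pytest.approx(q.quadratic)
        assert loaded.offset == pytest.approx(q.offset)

    def test_coo_text_contains_all_entries(self, rng):
        q = random_qubo(4, rng, density=1.0)
        lines = q.to_coo_text().strip().splitlines()
        assert len(lines) == 4 + q.n_couplings
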