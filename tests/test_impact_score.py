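"""Damped propagation, mutation penalty and win-rate conversion."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given
from hypothesis import strategies as st

from driverprog.impact_score import (
    apply_penalty,
    damping_vector,
    initial_scores,
    propagate,
    win_rate,
)


def brute_force_win_rate(S, mutated_mask):
    """Independent oracle: explicit pairwise comparisons with tie = 0.5."""
    n = S.size
    V = np.zeros(n)
    mut_idx = np.flatnonzero(mutated_mask)
    for g in range(n):
        if mutated_mask[g]:
            comp = [h for h in range(n) if h != g]
        else:
            comp = list(mut_idx)
        wins = sum(1.0 if S[h] < S[g] else 0.5 if S[h] == S[g] else 0.0 for h in comp)
        V[g] = wins / len(comp)
    return V


def linear_solve_impact(W_norm, f, d):
    """Closed-form fixed point (I - diag(d) W) S = diag(1-d) f."""
    n = f.size
    M = np.eye(n) - np.diag(d) @ W_norm.toarray()
    return np.linalg.solve(M, (1.0 - d) * f)


class TestDamping:
    @pytest.mark.parametrize("deg, expected", [(0, 0.0), (3, 0.5), (6, 2.0 / 3.0)])
    def test_closed_form(self, deg, expected):
        assert damping_vector(np.array([deg]))[0] == pytest.approx(expected)

    def test_negative_degree_rejected(self):
        with pytest.raises(ValueError):
            damping_vector(np.array([-1]))


class TestInitialScores:
    def test_absolute_difference(self):
        f = initial_scores(np.array([5.0, 10.0, 0.0]), np.array([8.0, 0.0, 10.0]))
        assert f.tolist() == [3.0, 10.0, 10.0]

    def test_identical_vectors_give_zero(self):
        v = np.array([1.0, 2.0])
        assert initial_scores(v, v).tolist() == [0.0, 0.0]

    def test_normalized_sums_to_one(self):
        f = initial_scores(np.array([5.0, 1.0]), np.array([1.0, 2.0]), normalize=True)
        assert f.sum() == pytest.approx(1.0)


class TestPropagate:
    def test_zero_damping_returns_f(self):
        W = sp.eye(3, format="csr")
        f = np.array([1.0, 2.0, 3.0])
        res = propagate(W, f, np.zeros(3))
        assert np.allclose(res.S, f)
        assert res.converged

    def test_two_gene_fixed_point(self):
        # edge g1 -> g2: W_norm[1, 0] = 1; d = (0, 1/4); f = (1, 0)
        # S1 = 1; S2 = (3/4)*0 + (1/4)*S1 = 1/4
        W = sp.csr_matrix(np.array([[0.0, 0.0], [1.0, 0.0]]))
        res = propagate(W, np.array([1.0, 0.0]), np.array([0.0, 0.25]), tol=1e-12)
        assert np.allclose(res.S, [1.0, 0.25])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_linear_solve_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 80)
        dense = rng.random((n, n)) * (rng.random((n, n)) < 0.1)
        np.fill_diagonal(dense, 0.0)
        col = dense.sum(axis=0)
        col[col == 0] = 1.0
        W = sp.csr_matrix(dense / col)
        f = rng.random(n)
        d = rng.random(n) * 0.9
        res = propagate(W, f, d, tol=1e-12, max_iter=5000)
        assert np.max(np.abs(res.S - linear_solve_impact(W, f, d))) <= 1e-8

    def test_linear_in_f(self, rng):
        n = 30
        dense = rng.random((n, n)) * (rng.random((n, n)) < 0.2)
        np.fill_diagonal(dense, 0.0)
        col = dense.sum(axis=0)
        col[col == 0] = 1.0
        W = sp.csr_matrix(dense / col)
        f = rng.random(n)
        d = rng.random(n) * 0.8
        S1 = propagate(W, f, d, tol=1e-12).S
        S2 = propagate(W, 3.0 * f, d, tol=1e-12).S
        assert np.allclose(S2, 3.0 * S1, atol=1e-6)

    def test_nonconvergence_is_flagged_not_fatal(self):
        W = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        res = propagate(W, np.array([1.0, 0.0]), np.array([0.999, 0.999]), tol=1e-14, max_iter=3)
        assert not res.converged
        assert res.iterations == 3


class TestPenalty:
    def test_mutated_gene_keeps_score(self):
        S = apply_penalty(np.array([0.4]), np.array([True]), p=0.85)
        assert S[0] == 0.4

    def test_non_mutated_gene_scaled(self):
        S = apply_penalty(np.array([0.4]), np.array([False]), p=0.85)
        assert S[0] == pytest.approx(0.34)

    def test_unit_penalty_is_identity(self, rng):
        S = rng.random(50)
        mask = rng.random(50) < 0.3
        assert np.array_equal(apply_penalty(S, mask, p=1.0), S)

    def test_invalid_penalty(self):
        with pytest.raises(ValueError):
            apply_penalty(np.ones(2), np.zeros(2, bool), p=0.0)


class TestWinRate:
    def test_five_gene_worked_example(self):
        # g1=0.9 (mut), g2=0.5, g3=0.2, g4=0.7, g5=0.1 (mut)
        S = np.array([0.9, 0.5, 0.2, 0.7, 0.1])
        mut = np.array([True, False, False, False, True])
        V = win_rate(S, mut).V
        assert V[0] == pytest.approx(1.0)  # beats all 4 others
        assert V[4] == pytest.approx(0.0)  # beats none
        assert V[1] == pytest.approx(0.5)  # beats g5, loses to g1

    def test_all_tied_scores_give_half(self):
        V = win_rate(np.ones(6), np.array([True, True, False, False, False, False])).V
        assert np.allclose(V, 0.5)

    def test_single_mutated_maximum_wins_everything(self):
        S = np.array([0.1, 0.2, 0.9, 0.3])
        mut = np.array([False, False, True, False])
        assert win_rate(S, mut).V[2] == pytest.approx(1.0)

    def test_no_mutations_falls_back_to_global_rank(self, caplog):
        S = np.array([1.0, 2.0, 3.0])
        with caplog.at_level("WARNING"):
            V = win_rate(S, np.zeros(3, bool)).V
        assert np.allclose(V, [0.0, 0.5, 1.0])
        assert any("no mutated genes" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        S = np.round(rng.random(n), 2)  # rounding forces ties
        mut = rng.random(n) < 0.3
        if not mut.any():
            mut[0] = True
        assert np.allclose(win_rate(S, mut).V, brute_force_win_rate(S, mut))

    @given(st.integers(0, 1000))
    def test_invariant_under_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        S = rng.random(20)
        mut = rng.random(20) < 0.4
        if not mut.any():
            mut[3] = True
        V1 = win_rate(S, mut).V
        V2 = win_rate(np.exp(5 * S), mut).V
        assert np.allclose(V1, V2)

    def test_values_in_unit_interval(self, rng):
        S = rng.random(100)
        mut = rng.random(100) < 0.1
        mut[0] = True
        V = win_rate(S, mut).V
        assert (V >= 0).all() and (V <= 1).all()
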