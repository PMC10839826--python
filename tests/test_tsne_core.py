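import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptltsne.tsne_core import (
    DegenerateRowError,
    calibrate_sigma,
    calibrate_sigmas,
    conditional_affinities,
    direct_embed,
    joint_affinities,
    kl_gradient,
    kl_loss,
    squared_distances,
    student_t_affinities,
    _row_perplexity,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles (plain python double loops)


def oracle_conditional(d2, sigmas):
    n = len(d2)
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        total = 0.0
        for j in range(n):
            if j != i:
                total += np.exp(-d2[i][j] / (2 * sigmas[i] ** 2))
        for j in range(n):
            if j != i:
                out[i][j] = np.exp(-d2[i][j] / (2 * sigmas[i] ** 2)) / total
    return np.array(out)


def oracle_joint(cond):
    n = len(cond)
    return np.array(
        [[(cond[i][j] + cond[j][i]) / (2 * n) for j in range(n)] for i in range(n)]
    )


def oracle_student_t(S):
    n = len(S)
    K = [[0.0] * n for _ in range(n)]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                d2 = sum((S[i][k] - S[j][k]) ** 2 for k in range(len(S[0])))
                K[i][j] = 1.0 / (1.0 + d2)
                total += K[i][j]
    return np.array(K) / total


def oracle_kl(P, Q):
    n = len(P)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and P[i][j] > 0:
                total += P[i][j] * np.log(P[i][j] / Q[i][j])
    return total


class TestConditionalAffinities:
    def test_two_points(self):
        d2 = np.array([[0.0, 3.0], [3.0, 0.0]])
        p = conditional_affinities(d2, np.array([0.7, 2.0]))
        assert p[0, 1] == 1.0 and p[1, 0] == 1.0

    def test_three_equidistant(self):
        d2 = np.full((3, 3), 2.0)
        np.fill_diagonal(d2, 0.0)
        p = conditional_affinities(d2, np.ones(3))
        off = p[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.5, atol=1e-15)

    def test_hand_arithmetic(self):
        """d2_12 = 1, d2_13 = 4, sigma_1 = 1."""
        d2 = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 1.0], [4.0, 1.0, 0.0]])
        p = conditional_affinities(d2, np.ones(3))
        expect = np.exp(-0.5) / (np.exp(-0.5) + np.exp(-2.0))
        assert p[0, 1] == pytest.approx(expect, abs=1e-14)

    def test_matches_oracle(self, rng):
        Z = rng.normal(size=(12, 3))
        d2 = squared_distances(Z)
        sig = rng.uniform(0.5, 2.0, size=12)
        assert np.abs(conditional_affinities(d2, sig) - oracle_conditional(d2, sig)).max() < 1e-12


class TestCalibrateSigma:
    def test_equidistant_row_any_sigma(self):
        row = np.full(9, 5.0)
        sigma, _ = calibrate_sigma(row, target_perplexity=9.0)
        assert _row_perplexity(row, sigma) == pytest.approx(9.0, abs=1e-9)

    def test_bad_target(self):
        with pytest.raises(ValueError):
            calibrate_sigma(np.array([1.0, 2.0]), target_perplexity=0.5)

    def test_grid_scan_oracle(self):
        """Row (1, 4, 9), target 2.0: bisection must agree with a fine
        independent sigma grid scan."""
        row = np.array([1.0, 4.0, 9.0])
        sigma, conv = calibrate_sigma(row, 2.0, tol=1e-7)
        assert conv
        assert _row_perplexity(row, sigma) == pytest.approx(2.0, abs=1e-4)
        grid = np.exp(np.linspace(np.log(1e-2), np.log(1e2), 200001))
        perr = np.array([abs(_row_perplexity(row, s) - 2.0) for s in grid])
        s_best = grid[perr.argmin()]
        assert sigma == pytest.approx(s_best, rel=1e-3)

    def test_monotone_in_sigma(self, rng):
        row = rng.uniform(0.1, 5.0, size=20)
        sigmas = np.exp(np.linspace(-2, 2, 30))
        perps = [_row_perplexity(row, s) for s in sigmas]
        assert np.all(np.diff(perps) >= -1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_calibration_hits_target(self, seed):
        """Property: random rows reach the target perplexity within tol."""
        r = np.random.default_rng(seed)
        n = int(r.integers(20, 80))
        row = r.uniform(0.05, 10.0, size=n) ** 2
        target = float(r.uniform(2.0, n * 0.7))
        sigma, conv = calibrate_sigma(row, target, tol=1e-5)
        assert conv
        assert abs(_row_perplexity(row, sigma) - target) <= 1e-4

    def test_vectorized_matches_scalar(self, rng):
        Z = rng.normal(size=(40, 4))
        d2 = squared_distances(Z)
        sig_vec = calibrate_sigmas(d2, 10.0, tol=1e-6)
        mask = ~np.eye(40, dtype=bool)
        for i in range(0, 40, 7):
            s, _ = calibrate_sigma(d2[i][mask[i]], 10.0, tol=1e-6)
            assert _row_perplexity(d2[i][mask[i]], sig_vec[i]) == pytest.approx(
                _row_perplexity(d2[i][mask[i]], s), abs=1e-5
            )


class TestJointAffinities:
    def test_invariants_random(self, rng):
        Z = rng.normal(size=(50, 4))
        am = joint_affinities(Z, perplexity=12.0)
        assert am.P.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.array_equal(am.P, am.P.T)
        assert np.all(np.diag(am.P) == 0)
        assert np.all(am.P >= 0)

    def test_three_equidistant_uniform(self):
        d2 = np.full((3, 3), 2.0)
        np.fill_diagonal(d2, 0.0)
        am = joint_affinities(np.zeros((3, 2)), perplexity=1.9, sq_dists=d2)
        off = am.P[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0 / 6.0, atol=1e-12)

    def test_two_cluster_structure_vs_oracle(self, rng):
        Z = np.array([[0.0, 0], [0.1, 0], [5.0, 0], [5.1, 0]])
        am = joint_affinities(Z, perplexity=2.0)
        within = am.P[0, 1]
        between = am.P[0, 2]
        assert within > between
        d2 = squared_distances(Z)
        oracle = oracle_joint(oracle_conditional(d2, am.sigmas))
        assert np.abs(am.P - oracle).max() < 1e-12

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        Z = rng.normal(size=(30, 3))
        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        am1 = joint_affinities(Z, 8.0)
        am2 = joint_affinities(Z @ R.T + np.array([1.0, -2.0, 0.5]), 8.0)
        assert np.abs(am1.P - am2.P).max() < 1e-9

    def test_identical_points_rejected(self):
        with pytest.raises(DegenerateRowError):
            joint_affinities(np.zeros((5, 2)), 2.0)


class TestStudentT:
    def test_identical_points_uniform(self):
        q = student_t_affinities(np.zeros((3, 2)))
        off = q.Q[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0 / 6.0, atol=1e-15)

    def test_hand_arithmetic(self):
        S = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        q = student_t_affinities(S)
        expect = 0.5 / (0.5 + 0.2 + 1.0 / 6.0)
        assert 2 * q.Q[0, 1] == pytest.approx(expect, abs=1e-14)

    def test_kernel_monotone_in_distance(self, rng):
        S = rng.normal(size=(10, 2))
        K1 = 1.0 / (1.0 + squared_distances(S))
        K2 = 1.0 / (1.0 + squared_distances(2 * S))
        off = ~np.eye(10, dtype=bool)
        assert np.all(K2[off] < K1[off])

    def test_matches_oracle(self, rng):
        S = rng.normal(size=(15, 2))
        assert np.abs(student_t_affinities(S).Q - oracle_student_t(S)).max() < 1e-12


class TestKLLoss:
    def test_zero_at_p_equals_q(self, rng):
        S = rng.normal(size=(8, 2))
        Q = student_t_affinities(S)
        assert abs(kl_loss(Q.Q, Q)) < 1e-12

    def test_nonnegative(self, rng):
        for _ in range(100):
            P = rng.uniform(size=(6, 6))
            np.fill_diagonal(P, 0)
            P = (P + P.T) / 2
            P /= P.sum()
            Q = rng.uniform(size=(6, 6))
            np.fill_diagonal(Q, 0)
            Q = (Q + Q.T) / 2
            Q /= Q.sum()
            assert kl_loss(P, Q) >= -1e-12

    def test_matches_double_loop_oracle(self, rng):
        Z = rng.normal(size=(4, 3))
        S = rng.normal(size=(4, 2))
        P = joint_affinities(Z, 2.0)
        Q = student_t_affinities(S)
        assert kl_loss(P, Q) == pytest.approx(oracle_kl(P.P, Q.Q), abs=1e-12)

    def test_replacing_q_by_p_decreases(self, rng):
        Z = rng.normal(size=(10, 3))
        P = joint_affinities(Z, 4.0)
        Q = student_t_affinities(rng.normal(size=(10, 2)))
        assert kl_loss(P, P.P) <= kl_loss(P, Q) + 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            kl_loss(np.zeros((3, 3)), np.zeros((4, 4)))


class TestGradientAndDirectEmbed:
    def test_gradient_matches_finite_differences(self, rng):
        Z = rng.normal(size=(12, 3))
        P = joint_affinities(Z, 5.0).P
        S = rng.normal(size=(12, 2))
        _, g = kl_gradient(P, S)
        h = 1e-6
        for idx in [(0, 0), (3, 1), (11, 0)]:
            Sp, Sm = S.copy(), S.copy()
            Sp[idx] += h
            Sm[idx] -= h
            num = (kl_gradient(P, Sp)[0] - kl_gradient(P, Sm)[0]) / (2 * h)
            assert g[idx] == pytest.approx(num, abs=1e-6)

    def test_direct_embed_reduces_loss(self, rng):
        Z = rng.normal(size=(60, 5))
        P = joint_affinities(Z, 10.0)
        S0 = np.random.default_rng(0).normal(0, 1e-2, size=(60, 2))
        l0, _ = kl_gradient(P.P, S0)
        S = direct_embed(P, n_iter=200, seed=0)
        l1, _ = kl_gradient(P.P, S)
        assert l1 < l0
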