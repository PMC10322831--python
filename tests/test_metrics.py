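"""Reference metrics against closed-form oracles and limiting cases."""

import itertools

import numpy as np
import pytest
from scipy.linalg import solve_discrete_lyapunov

from rsnphi import (BinaryTimeSeries, GroundTruthNetwork, causal_density,
                    fit_var, make_coupled_tpm, mean_correlation, phi_star,
                    simulate_binary_series)
from rsnphi.metrics import (_balanced_bipartitions, _lagged_state_pairs,
                            _part_index, _plugin_mi)
from rsnphi.states import all_states


# ---------------------------------------------------------------------------
# closed-form oracles

def stationary_distribution(tpm: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(tpm.T)
    pi = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    pi = np.abs(pi)
    return pi / pi.sum()


def chain_lag1_mi(tpm: np.ndarray, part: tuple[int, ...], n_nodes: int
                  ) -> float:
    """Exact lag-1 MI (nats) of a node subset of a stationary Markov chain."""
    pi = stationary_distribution(tpm)
    joint_full = pi[:, None] * tpm
    bits = all_states(n_nodes)
    pw = 1 << np.arange(len(part))
    sub = bits[:, list(part)] @ pw
    k = 2 ** len(part)
    joint = np.zeros((k, k))
    for i in range(tpm.shape[0]):
        for j in range(tpm.shape[0]):
            joint[sub[i], sub[j]] += joint_full[i, j]
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * (np.log(joint[nz])
                                     - np.log(np.outer(px, py)[nz]))))


def chain_lag1_mi_pair(sa, sb) -> float:
    """Empirical Phi* value at the bipartition aligned with two blocks."""
    joint = BinaryTimeSeries(
        np.concatenate([sa.values, sb.values], axis=1), list("abcd"))
    past, present = _lagged_state_pairs(joint, 1)
    whole = _plugin_mi(_part_index(past, (0, 1, 2, 3)),
                       _part_index(present, (0, 1, 2, 3)), 16, 16)
    parts = sum(_plugin_mi(_part_index(past, p), _part_index(present, p),
                           4, 4) for p in ((0, 1), (2, 3)))
    return whole - parts


def analytic_bivariate_granger(a_mat, sigma, p):
    """F(x -> y) for a stationary VAR(1), restricted model of order p."""
    g0 = solve_discrete_lyapunov(a_mat, sigma)
    gs = [g0]
    for _ in range(p):
        gs.append(a_mat @ gs[-1])
    gy = [g[1, 1] for g in gs]
    big_r = np.array([[gy[abs(i - j)] for j in range(p)] for i in range(p)])
    r = np.array([gy[i + 1] for i in range(p)])
    restricted = gy[0] - np.linalg.solve(big_r, r) @ r
    return float(np.log(restricted / sigma[1, 1]))


# ---------------------------------------------------------------------------
# Phi*

class TestPhiStar:
    def test_ten_bipartitions_for_five_regions(self):
        parts = _balanced_bipartitions(5)
        assert len(parts) == 10
        assert all({len(a), len(b)} == {2, 3} for a, b in parts)

    def test_iid_coins_vanishes(self, rng):
        values = rng.integers(0, 2, (20_000, 4))
        res = phi_star(BinaryTimeSeries(values, list("abcd")))
        assert abs(res.phi_star) < 0.01
        assert res.whole_mi < 0.02

    def test_independent_blocks_vanish_at_aligned_split(self):
        """Two independent sub-chains: whole MI = sum of part MIs, so the
        aligned bipartition drives Phi* to zero."""
        net_a = GroundTruthNetwork(2, make_coupled_tpm(2, 0.9, seed=0), 0.9)
        net_b = GroundTruthNetwork(2, make_coupled_tpm(2, 0.9, seed=1), 0.9)
        sa = simulate_binary_series(net_a, 30_000, seed=2)
        sb = simulate_binary_series(net_b, 30_000, seed=3)
        joint = BinaryTimeSeries(
            np.concatenate([sa.values, sb.values], axis=1), list("abcd"))
        res = phi_star(joint)
        # at the aligned split, whole MI = sum of part MIs
        aligned = chain_lag1_mi_pair(sa, sb)
        assert aligned == pytest.approx(0.0, abs=0.02)
        # the reported minimum can only be lower still
        assert res.phi_star <= aligned + 1e-12

    @pytest.mark.parametrize("length", [2_000, 10_000, 50_000])
    def test_matches_closed_form_mi(self, length):
        """Plug-in estimates approach the chain's exact lag-1 MI."""
        tpm = make_coupled_tpm(4, 0.6, seed=4)
        net = GroundTruthNetwork(4, tpm, 0.6)
        series = simulate_binary_series(net, length, seed=6)
        res = phi_star(series)
        n = 4
        whole_exact = chain_lag1_mi(tpm.probs, tuple(range(n)), n)
        tol = 40.0 / length + 0.02
        assert res.whole_mi == pytest.approx(whole_exact, abs=tol)
        exact_star = min(
            whole_exact - chain_lag1_mi(tpm.probs, p1, n)
            - chain_lag1_mi(tpm.probs, p2, n)
            for p1, p2 in _balanced_bipartitions(n))
        assert res.phi_star == pytest.approx(exact_star, abs=3 * tol)

    def test_phi_star_bounded_by_whole_mi(self, coupled_3node_series):
        res = phi_star(coupled_3node_series)
        assert res.phi_star <= res.whole_mi + 1e-12
        assert res.whole_mi >= 0
        assert all(m >= 0 for m in res.part_mis)

    def test_too_short_series(self):
        s = BinaryTimeSeries(np.zeros((1, 2), dtype=int), ["a", "b"])
        with pytest.raises(ValueError):
            phi_star(s, tau=5)


# ---------------------------------------------------------------------------
# VAR and causal density

class TestFitVar:
    def test_noiseless_ar1_recovered_exactly(self):
        x = np.zeros((500, 2))
        x[0] = [1.0, -1.0]
        for t in range(1, 500):
            x[t] = [0.9 * x[t - 1, 0], 0.7 * x[t - 1, 1]]
        fit = fit_var(x, p_max=1)
        assert fit.order_p == 1
        assert np.allclose(np.diag(fit.coefs[0]), [0.9, 0.7], atol=1e-6)

    def test_noiseless_higher_order_is_rank_deficient(self):
        x = np.zeros((200, 2))
        x[0] = [1.0, -1.0]
        for t in range(1, 200):
            x[t] = 0.9 * x[t - 1]
        with pytest.raises(np.linalg.LinAlgError, match="rank-deficient"):
            fit_var(x, p_max=2)

    def test_agrees_with_statsmodels_var(self, rng):
        """Single-segment fits match the established VAR implementation."""
        from statsmodels.tsa.api import VAR

        a1 = np.array([[0.6, 0.15], [-0.1, 0.5]])
        x = np.zeros((3000, 2))
        e = rng.standard_normal((3000, 2))
        for t in range(1, 3000):
            x[t] = a1 @ x[t - 1] + e[t]
        ours = fit_var(x, p_max=1)
        ref = VAR(x).fit(1, trend="c")
        assert np.allclose(ours.coefs[0], ref.coefs[0], atol=1e-8)
        assert np.allclose(ours.intercept, ref.intercept, atol=1e-8)

    def test_white_noise_selects_minimal_order(self, rng):
        hits = sum(
            fit_var(np.random.default_rng(s).standard_normal((800, 2)),
                    p_max=5).order_p == 1
            for s in range(20))
        assert hits >= 18

    def test_segments_do_not_leak(self, rng):
        """Boundary rows are excluded: two short trials fit like one model."""
        from rsnphi.containers import Segment
        vals = rng.integers(0, 2, (400, 2))
        series = BinaryTimeSeries(vals, ["a", "b"],
                                  [Segment("x", 0, 200), Segment("y", 200, 200)])
        fit = fit_var(series, p_max=2)
        assert fit.n_obs == 400 - 2 * fit.order_p


class TestCausalDensity:
    def test_matches_analytic_bivariate_oracle(self):
        a_mat = np.array([[0.7, 0.0], [0.9, 0.3]])
        sigma = np.diag([1.0, 0.3])
        p = 2
        expected = analytic_bivariate_granger(a_mat, sigma, p)
        rng = np.random.default_rng(3)
        t_len = 10_000
        e = rng.multivariate_normal([0, 0], sigma, size=t_len)
        z = np.zeros((t_len, 2))
        for t in range(1, t_len):
            z[t] = a_mat @ z[t - 1] + e[t]
        res = causal_density(z, order=p)
        assert res.pairwise_F[0, 1] == pytest.approx(expected, rel=0.02)
        assert res.pairwise_F[1, 0] < 0.002

    def test_white_noise_near_zero(self, rng):
        z = rng.standard_normal((4_000, 3))
        res = causal_density(z, p_max=3)
        # asymptotic null scale of each F-hat is ~ p/T
        assert res.causal_density < 5 * res.order_p / 4_000

    def test_five_regions_average_twenty_values(self, rng):
        z = rng.standard_normal((600, 5))
        res = causal_density(z, p_max=2)
        off_diag = ~np.eye(5, dtype=bool)
        assert np.isfinite(res.pairwise_F[off_diag]).all()
        assert np.isnan(np.diag(res.pairwise_F)).all()
        assert res.causal_density == pytest.approx(
            res.pairwise_F[off_diag].mean())

    def test_affine_invariance(self, rng):
        z = rng.standard_normal((1_500, 3))
        a = causal_density(z, order=2)
        b = causal_density(z * np.array([3.0, 0.5, 10.0]) + 7.0, order=2)
        assert np.allclose(a.pairwise_F[~np.eye(3, dtype=bool)],
                           b.pairwise_F[~np.eye(3, dtype=bool)], atol=1e-8)


class TestMeanCorrelation:
    def test_identical_regions_give_one(self):
        base = np.random.default_rng(0).standard_normal(100)
        z = np.column_stack([base] * 4)
        assert mean_correlation(z).mu_rho == pytest.approx(1.0)

    def test_five_regions_ten_pairs(self, rng):
        z = rng.standard_normal((200, 5))
        res = mean_correlation(z)
        assert len(res.pairwise_rho) == 10
        assert all(-1 <= v <= 1 for v in res.pairwise_rho.values())

    def test_invariant_under_common_permutation(self, rng):
        z = rng.standard_normal((300, 4))
        perm = rng.permutation(300)
        assert mean_correlation(z).mu_rho == pytest.approx(
            mean_correlation(z[perm]).mu_rho, abs=1e-14)

    def test_constant_region_rejected(self):
        z = np.column_stack([np.ones(50), np.arange(50.0)])
        with pytest.raises(ValueError, match="constant"):
            mean_correlation(z)
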