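import numpy as np
import pytest

from tunneltransit import (ck_test, cluster_microstates, count_matrix,
                           implied_timescales, lump_metastable, mfpt,
                           rates_and_kd, simulate_markov_chain, tica,
                           transition_matrix)
from tunneltransit.msm import largest_connected_set, stationary_distribution


def ar1(n, tau, rng):
    phi = np.exp(-1.0 / tau)
    x = np.empty(n)
    x[0] = rng.normal()
    for t in range(1, n):
        x[t] = phi * x[t - 1] + np.sqrt(1 - phi**2) * rng.normal()
    return x


class TestTICA:
    def test_single_feature_identity_up_to_scale(self):
        rng = np.random.default_rng(0)
        x = ar1(2000, 20, rng)[:, None]
        res = tica(x, lag=5, n_dims=1)
        c = np.corrcoef(res.coords[:, 0], x[:, 0])[0, 1]
        assert abs(c) > 1 - 1e-9

    def test_recovers_planted_slow_mode(self):
        rng = np.random.default_rng(1)
        slow, fast = ar1(5000, 100, rng), ar1(5000, 2, rng)
        S = np.column_stack([slow, fast])
        A = np.array([[0.7, 0.4], [0.3, -0.6]])
        res = tica(S @ A.T, lag=10, n_dims=2)
        corr = np.corrcoef(res.coords[:, 0], slow)[0, 1]
        assert abs(corr) >= 0.9

    def test_white_noise_eigenvalues_near_zero(self):
        rng = np.random.default_rng(2)
        n = 20000
        res = tica(rng.normal(size=(n, 4)), lag=3, n_dims=4)
        assert np.all(np.abs(res.eigenvalues) < 3.0 / np.sqrt(n))

    def test_lag_too_large_rejected(self):
        with pytest.raises(ValueError):
            tica(np.zeros((5, 2)), lag=5)


class TestMicrostates:
    def test_separated_blobs_pure(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.3, (100, 2))
        b = rng.normal(10, 0.3, (100, 2))
        labels, _ = cluster_microstates(np.vstack([a, b]), 2, seed=0)
        assert len(set(labels[:100])) == 1
        assert len(set(labels[100:])) == 1
        assert labels[0] != labels[100]

    def test_k_one_single_state(self):
        labels, _ = cluster_microstates(np.random.default_rng(4).normal(size=(50, 2)),
                                        1, seed=0)
        assert set(labels) == {0}

    def test_same_seed_identical(self):
        X = np.random.default_rng(5).normal(size=(200, 3))
        a, _ = cluster_microstates(X, 10, seed=7)
        b, _ = cluster_microstates(X, 10, seed=7)
        assert np.array_equal(a, b)

    def test_k_exceeds_points_rejected(self):
        with pytest.raises(ValueError):
            cluster_microstates(np.zeros((3, 2)), 5, seed=0)


class TestCountMatrix:
    def test_hand_enumeration(self):
        C = count_matrix([np.array([0, 1, 0, 1])], lag=1)
        assert np.array_equal(C, [[0, 2], [1, 0]])

    def test_constant_trajectory(self):
        C = count_matrix([np.array([0, 0, 0])], lag=1)
        assert np.array_equal(C, [[2]])

    def test_no_pairs_across_trajectory_boundary(self):
        a, b = np.array([0, 1, 1]), np.array([1, 0, 0])
        sep = count_matrix([a, b], lag=1)
        joined = count_matrix([np.concatenate([a, b])], lag=1)
        diff = joined - sep
        assert diff.sum() == 1 and diff[1, 1] == 1   # only the boundary pair

    def test_lag_exhausts_data_rejected(self):
        with pytest.raises(ValueError, match="no transition pairs"):
            count_matrix([np.array([0, 1])], lag=5)


class TestTransitionMatrix:
    def test_hand_normalisation(self):
        P, pi, active = transition_matrix(np.array([[8, 2], [1, 9]]),
                                          reversible=False)
        assert np.allclose(P, [[0.8, 0.2], [0.1, 0.9]])
        assert np.allclose(pi @ P, pi, atol=1e-8)

    def test_symmetric_counts_modes_agree(self):
        C = np.array([[5, 3], [3, 7]])
        P_rev, _, _ = transition_matrix(C, reversible=True)
        P_non, _, _ = transition_matrix(C, reversible=False)
        assert np.allclose(P_rev, P_non)

    def test_rows_sum_to_one_and_stationarity(self):
        rng = np.random.default_rng(6)
        C = rng.integers(1, 50, size=(5, 5))
        for rev in (True, False):
            P, pi, _ = transition_matrix(C, reversible=rev)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.allclose(pi @ P, pi, atol=1e-8)

    def test_reversible_detailed_balance(self):
        rng = np.random.default_rng(7)
        C = rng.integers(1, 50, size=(4, 4))
        P, pi, _ = transition_matrix(C, reversible=True)
        flux = pi[:, None] * P
        assert np.allclose(flux, flux.T, atol=1e-8)

    def test_disconnected_counts_restricted(self):
        C = np.zeros((4, 4), dtype=int)
        C[:2, :2] = [[10, 5], [5, 10]]
        C[2, 2] = 1   # isolated self-looping state with few counts
        C[3, 3] = 1
        P, _, active = transition_matrix(C)
        assert set(active) == {0, 1}
        assert P.shape == (2, 2)

    def test_largest_connected_set_strong(self):
        C = np.array([[0, 5, 0], [5, 0, 0], [1, 0, 0]])  # 2 reaches 0, not back
        assert set(largest_connected_set(C)) == {0, 1}


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        # P = [[0.9, .1], [.2, .8]] has lambda_2 = 0.7
        P = np.array([[0.9, 0.1], [0.2, 0.8]])
        s = simulate_markov_chain(P, np.eye(2), 200000, seed=8, noise_sd=0.0)
        tab = implied_timescales([s.states], lags=[1, 2], reversible=False)
        expected = -1.0 / np.log(0.7)
        assert tab.loc[1, "t2"] == pytest.approx(expected, rel=0.05)

    def test_markovian_data_flat_across_lags(self):
        P = np.array([[0.95, 0.05], [0.1, 0.9]])
        s = simulate_markov_chain(P, np.eye(2), 200000, seed=9, noise_sd=0.0)
        tab = implied_timescales([s.states], lags=[1, 2, 4, 8], reversible=False)
        t = tab["t2"].to_numpy()
        assert np.all(np.abs(t / t[0] - 1.0) < 0.15)

    def test_identity_like_chain_has_no_finite_timescale(self):
        tab = implied_timescales([np.zeros(100, dtype=int),
                                  np.ones(100, dtype=int)], lags=[1, 2])
        assert "t2" not in tab.columns

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(10)
        P = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        s = simulate_markov_chain(P, np.eye(3), 50000, seed=11, noise_sd=0.0)
        perm = np.array([2, 0, 1])
        a = implied_timescales([s.states], lags=[1, 3])
        b = implied_timescales([perm[s.states]], lags=[1, 3])
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestLumping:
    def block_P(self, eps=0.01):
        blocks = [np.array([0, 1, 2]), np.array([3, 4]), np.array([5, 6, 7])]
        P = np.full((8, 8), eps / 8)
        for b in blocks:
            P[np.ix_(b, b)] += (1 - eps) / len(b)
        return P / P.sum(axis=1, keepdims=True), blocks

    def test_planted_blocks_recovered(self):
        P, blocks = self.block_P()
        lump = lump_metastable(P, 3, seed=0)
        for b in blocks:
            assert len(set(lump[b])) == 1
        assert len(set(lump)) == 3

    def test_identity_when_n_states_equals_k(self):
        P, _ = self.block_P()
        assert np.array_equal(lump_metastable(P, 8), np.arange(8))

    def test_permutation_equivariance(self):
        P, _ = self.block_P()
        perm = np.random.default_rng(12).permutation(8)
        Pp = P[np.ix_(perm, perm)]
        a = lump_metastable(P, 3, seed=0)
        b = lump_metastable(Pp, 3, seed=0)
        # same partition after mapping through the permutation
        pairs_a = {(i, j) for i in range(8) for j in range(8) if a[i] == a[j]}
        pairs_b = {(i, j) for i in range(8) for j in range(8)
                   if b[np.where(perm == i)[0][0]] == b[np.where(perm == j)[0][0]]}
        assert pairs_a == pairs_b


class TestMFPT:
    P2 = np.array([[0.9, 0.1], [0.2, 0.8]])

    def test_two_state_closed_form(self):
        assert mfpt(self.P2, [0], [1]) == pytest.approx(10.0)
        assert mfpt(self.P2, [1], [0]) == pytest.approx(5.0)

    def test_certain_step_equals_lag(self):
        P = np.array([[0.0, 1.0], [0.5, 0.5]])
        assert mfpt(P, [0], [1], lag_time=7.0) == pytest.approx(7.0)

    def test_monte_carlo_oracle_agreement(self):
        rng = np.random.default_rng(13)
        P = rng.dirichlet(np.ones(5) * 2.0, size=5)
        pi = stationary_distribution(P)
        analytic = mfpt(P, [0], [4], pi=pi)
        # stochastic oracle: direct first-passage simulation
        n_walk = 20000
        state = np.zeros(n_walk, dtype=int)
        steps = np.zeros(n_walk)
        active = np.ones(n_walk, dtype=bool)
        cum = np.cumsum(P, axis=1)
        mc_rng = np.random.default_rng(14)
        for _ in range(100000):
            if not active.any():
                break
            u = mc_rng.random(active.sum())
            nxt = np.array([np.searchsorted(cum[s], x, side="right")
                            for s, x in zip(state[active], u)])
            state[active] = np.minimum(nxt, 4)
            steps[active] += 1
            active &= state != 4
        se = steps.std() / np.sqrt(n_walk)
        assert abs(steps.mean() - analytic) < 2 * se + 1e-9

    def test_unreachable_sink_rejected(self):
        P = np.array([[1.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="absorbing failure"):
            mfpt(P, [0], [1])

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            mfpt(self.P2, [0], [0])


class TestRates:
    def test_arithmetic_and_symmetry(self):
        assert rates_and_kd(10.0, 10.0).k_d == pytest.approx(1.0)
        kin = rates_and_kd(10.0, 5.0)
        assert kin.k_d == pytest.approx(2.0)
        assert kin.k_on == pytest.approx(0.1)

    def test_time_rescaling_leaves_kd(self):
        a = rates_and_kd(10.0, 5.0)
        b = rates_and_kd(5.0, 2.5)
        assert a.k_d == pytest.approx(b.k_d)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rates_and_kd(np.inf, 1.0)


class TestCK:
    def test_factor_one_zero_deviation(self):
        P = np.array([[0.9, 0.1], [0.2, 0.8]])
        s = simulate_markov_chain(P, np.eye(2), 20000, seed=15, noise_sd=0.0)
        tab = ck_test([s.states], lag=1, factors=[1], n_macrostates=2,
                      n_boot=20, seed=0)
        assert np.allclose(tab["deviation"], 0.0, atol=1e-12)

    def test_markovian_within_band(self):
        P = np.array([[0.95, 0.04, 0.01], [0.05, 0.9, 0.05], [0.01, 0.09, 0.9]])
        trajs = [simulate_markov_chain(P, np.eye(3), 3000, seed=100 + i,
                                       noise_sd=0.0).states for i in range(20)]
        tab = ck_test(trajs, lag=2, factors=[2, 3, 4], n_macrostates=2,
                      n_boot=50, seed=1)
        assert tab["within_band"].all()

    def test_heavy_tailed_dwells_fail_at_factor_four(self):
        rng = np.random.default_rng(16)
        trajs = []
        for _ in range(50):
            seq, state = [], 0
            while len(seq) < 2000:
                dwell = int(min(rng.pareto(0.8) + 1, 1500))
                seq.extend([state] * dwell)
                state = 1 - state
            trajs.append(np.array(seq[:2000]))
        tab = ck_test(trajs, lag=1, factors=[4], n_macrostates=2,
                      n_boot=50, seed=2)
        assert not tab["within_band"].all()
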