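import numpy as np
import pytest
from scipy.linalg import expm

from sisnet import (EpidemicParams, Network, SimState, Trajectory,
                    endemic_prevalence_estimate, expected_rate_of_change,
                    gillespie_sis, generate_k_regular,
                    master_equation_oracle, naive_prevalence_estimate,
                    quasi_stationary_prevalence)


class TestGillespieBasics:
    def test_no_transmission_decays_to_extinction(self, ring8):
        params = EpidemicParams(tau=0.0, gamma=1.0)
        ext_times = []
        for s in range(200):
            traj = gillespie_sis(ring8, params, initial_infected=4,
                                 t_max=100.0, seed=s, record_interval=0.25)
            assert np.all(np.diff(traj.I) <= 0)
            assert traj.I[-1] == 0
            ext_times.append(traj.times[-1])
        # extinction time = max of 4 Exp(1) variables; E = H_4 = 25/12
        ext = np.array(ext_times)
        se = ext.std(ddof=1) / np.sqrt(len(ext))
        assert abs(ext.mean() - 25.0 / 12.0) < 3 * se

    def test_no_recovery_absorbs_at_full_infection(self, ring8):
        params = EpidemicParams(tau=1.0, gamma=0.0)
        traj = gillespie_sis(ring8, params, initial_infected=[0],
                             t_max=500.0, seed=1)
        assert traj.I[-1] == ring8.N

    def test_empty_initial_infection_rejected(self, ring8, params11):
        with pytest.raises(ValueError):
            gillespie_sis(ring8, params11, initial_infected=[], t_max=1.0)

    def test_seed_determinism(self, regular_k3_small, params11):
        a = gillespie_sis(regular_k3_small, params11, 50, 10.0, seed=3)
        b = gillespie_sis(regular_k3_small, params11, 50, 10.0, seed=3)
        np.testing.assert_array_equal(a.I, b.I)
        np.testing.assert_array_equal(a.SI, b.SI)

    def test_pair_slot_conservation(self, regular_k3_small, params11):
        traj = gillespie_sis(regular_k3_small, params11, 100, 20.0, seed=4)
        total = traj.SS + 2 * traj.SI + traj.II
        assert np.all(total == sum(regular_k3_small.degree_sequence))
        assert np.all(traj.S + traj.I == regular_k3_small.N)


class TestMasterEquationOracle:
    def test_two_node_chain_against_dense_matrix_exponential(self):
        edge = Network.from_edges(2, [(0, 1)])
        params = EpidemicParams(tau=1.0, gamma=1.0)
        t_grid = np.linspace(0, 4, 9)
        traj = master_equation_oracle(edge, params, [1, 0], t_grid)
        # independent oracle: hand-built 4-state generator, dense expm
        # states 0:SS 1:IS 2:SI 3:II
        Q = np.zeros((4, 4))
        Q[0, 1] = Q[0, 2] = 1.0          # recovery into SS
        Q[3, 1] = Q[3, 2] = 1.0          # infection of the S partner
        Q[1, 3] = Q[2, 3] = 1.0          # recovery of one of two I
        gen = Q - np.diag(Q.sum(axis=0))  # column-stochastic generator
        nI = np.array([0, 1, 1, 2])
        for t, ei in zip(t_grid, traj.I):
            p = expm(gen * t) @ np.array([0, 1, 0, 0.0])
            assert ei == pytest.approx(float(p @ nI), abs=1e-8)

    def test_pure_death_is_exponential(self, ring8):
        params = EpidemicParams(tau=0.0, gamma=1.0)
        t_grid = np.linspace(0, 3, 7)
        traj = master_equation_oracle(ring8, params,
                                      [1, 1, 0, 0, 0, 0, 0, 0], t_grid)
        np.testing.assert_allclose(traj.I, 2 * np.exp(-t_grid), atol=1e-9)

    def test_oracle_size_limit(self, params11):
        big = generate_k_regular(20, 3, seed=0, min_girth=2)
        with pytest.raises(ValueError):
            master_equation_oracle(big, params11, [1] + [0] * 19, [0, 1])

    def test_gillespie_ensemble_matches_oracle(self, ring8, params11):
        t_grid = np.linspace(0, 3, 7)
        oracle = master_equation_oracle(ring8, params11,
                                        [1, 0, 0, 0, 0, 0, 0, 0], t_grid)
        reps = 3000
        samples = np.zeros((reps, len(t_grid)))
        for s in range(reps):
            traj = gillespie_sis(ring8, params11, initial_infected=[0],
                                 t_max=3.0, seed=s, record_interval=0.5)
            samples[s] = np.interp(t_grid, traj.times, traj.I,
                                   right=traj.I[-1])
        mean = samples.mean(axis=0)
        se = samples.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean[1:] - oracle.I[1:]) < 3 * se[1:])


class TestExpectedRate:
    def test_all_susceptible_state_is_zero(self, ring8, params11):
        state = SimState.from_states(ring8, np.zeros(8))
        assert expected_rate_of_change(state, params11) == 0.0

    def test_single_edge_direct_substitution(self):
        edge = Network.from_edges(2, [(0, 1)])
        state = SimState.from_states(edge, [0, 1])
        assert expected_rate_of_change(state, EpidemicParams(2.0, 1.0)) == 1.0

    def test_matches_bruteforce_event_rates(self, params11):
        net = generate_k_regular(20, 3, seed=2, min_girth=2)
        adj = net.adjacency_lists()
        rng = np.random.default_rng(0)
        for _ in range(25):
            states = rng.integers(0, 2, size=20)
            brute = 0.0
            for i in range(20):
                if states[i] == 0:
                    brute += params11.tau * sum(states[j] for j in adj[i])
                else:
                    brute -= params11.gamma
            sim_state = SimState.from_states(net, states)
            assert expected_rate_of_change(sim_state, params11) == \
                pytest.approx(brute)


class TestEndemicEstimator:
    def _synthetic(self, root, slope, noise, params, n=200, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n) * 0.5
        I = root + rng.normal(0, 60, size=n)
        r = slope * (I - root) + rng.normal(0, noise, size=n)
        SI = (r + params.gamma * I) / params.tau
        return Trajectory(times=t, I=I, SI=SI, SS=np.zeros(n),
                          II=np.zeros(n), N=10000)

    def test_recovers_known_linear_root(self, params11):
        traj = self._synthetic(4000.0, -0.5, 5.0, params11)
        est, se, flag = endemic_prevalence_estimate(traj, params11,
                                                    burn_in=0.0)
        assert not flag
        assert abs(est - 4000.0) < max(3 * se, 1.0)

    def test_exact_fixed_point_returned_exactly(self, params11):
        n = 40
        traj = Trajectory(times=np.arange(n) * 1.0,
                          I=np.full(n, 4000.0), SI=np.full(n, 4000.0),
                          SS=np.zeros(n), II=np.zeros(n), N=10000)
        est, se, flag = endemic_prevalence_estimate(traj, params11,
                                                    burn_in=0.0)
        assert flag and est == 4000.0

    def test_variance_below_naive_time_average(self, params11):
        net = generate_k_regular(2500, 3, seed=6)
        rate_based, naive = [], []
        for s in range(50):
            traj = gillespie_sis(net, params11, initial_infected=1250,
                                 t_max=60.0, seed=100 + s,
                                 record_interval=0.5, qs_restart=True)
            est, _, _ = endemic_prevalence_estimate(traj, params11)
            rate_based.append(est)
            naive.append(naive_prevalence_estimate(traj, params11)[0])
        assert np.var(rate_based, ddof=1) < np.var(naive, ddof=1)


class TestQuasiStationary:
    def test_complete_graph_matches_meanfield_fixed_point(self):
        N = 200
        net = Network.from_edges(N, [(i, j) for i in range(N)
                                     for j in range(i + 1, N)])
        params = EpidemicParams(tau=2.0 / (N - 1), gamma=1.0)
        vals = []
        for s in range(4):
            mI, _, _ = quasi_stationary_prevalence(
                net, params, t_burn=30.0, t_meas=150.0, seed=s)
            vals.append(mI / N)
        vals = np.array(vals)
        se = max(vals.std(ddof=1) / np.sqrt(len(vals)), 0.005)
        assert abs(vals.mean() - 0.5) < 3 * se

    def test_long_window_balances_rates(self, regular_k3_small, params11):
        # endemic balance: time-averaged tau<SI> approaches gamma<I>
        mI, mSI, _ = quasi_stationary_prevalence(
            regular_k3_small, params11, t_burn=100.0, t_meas=500.0, seed=8)
        assert params11.tau * mSI == pytest.approx(params11.gamma * mI,
                                                   rel=0.02)
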