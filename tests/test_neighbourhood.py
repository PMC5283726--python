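import numpy as np
import pytest

from sisnet import (EpidemicParams, build_chain_motif_model,
                    build_neighbourhood_family, build_neighbourhood_n2,
                    build_neighbourhood_n3, build_pairwise, count_equations,
                    solve_endemic)

N = 10000.0


class TestCountEquations:
    @pytest.mark.parametrize("degrees,n,expected", [
        ({2}, 2, 5), ({3}, 2, 7), ({1, 2}, 2, 27), ({1, 2, 3}, 2, 165),
        ({1, 2, 3}, 3, 65015)])
    def test_printed_counts(self, degrees, n, expected):
        assert count_equations(degrees, n) == expected

    def test_homogeneous_matches_model_dimension(self, params11):
        for k in (2, 3):
            model = build_neighbourhood_n2(N, k, params11)
            assert model.dimension == count_equations({k}, 2)

    def test_n3_ball_count_matches_model(self, params11):
        for k in (2, 3):
            model = build_neighbourhood_n3(N, k, params11)
            assert model.dimension == count_equations({k}, 3)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            count_equations({1, 2}, 4)
        with pytest.raises(ValueError):
            count_equations(set(), 2)


class TestN2:
    def test_force_of_infection_on_concentrated_state(self, params11):
        """With all susceptible mass in S_1, the force on a susceptible
        neighbour of an infectious centre is exactly tau (the centre
        itself): lambda_I = tau * 1^2 S_1 / (1 * S_1)."""
        k = 3
        model = build_neighbourhood_n2(N, k, params11)
        y = np.zeros(2 * (k + 1))
        y[1] = 0.7 * N          # S_1
        y[k + 1 + 2] = 0.3 * N  # I_2 (irrelevant to lambda)
        dy = model.rhs(y)
        # S_1 outflux: centre infection tau*1*S_1, lambda_S*(k-1)*S_1 with
        # lambda_S = tau * (k-1)*1*S_1/((k-1)*S_1) = tau, neighbour
        # recovery gamma*1*S_1; influx gamma*(2)*S_2 = 0, lambda_S*k*S_0=0
        tau, gamma = params11.tau, params11.gamma
        expected = -(tau * 1 + tau * (k - 1) + gamma * 1) * y[1]
        assert dy[1] == pytest.approx(expected, rel=1e-12)

    def test_conservation_and_consistency_at_independence(self, params11):
        k = 3
        model = build_neighbourhood_n2(N, k, params11)
        y0 = model.initial_state(0.2)
        ks = np.arange(k + 1)
        S, I = y0[:k + 1], y0[k + 1:]
        # sum_y y ([S_y] + [I_y]) counts infectious ends of edges = k [I]
        assert (ks * (S + I)).sum() == pytest.approx(k * I.sum(), rel=1e-12)
        t = np.linspace(0, 25, 11)
        _, Y = model.integrate(y0, t)
        assert model.check_conservation(Y) < 1e-8

    def test_lambda_zero_when_no_susceptible_neighbours(self, params11):
        k = 2
        model = build_neighbourhood_n2(N, k, params11)
        y = np.zeros(2 * (k + 1))
        y[k + 1 + k] = N  # all mass in I_k: no S anywhere
        dy = model.rhs(y)
        # only recoveries act: centre (gamma) and neighbours (gamma*k)
        assert dy[k + 1 + k] == pytest.approx(-(1 + k) * model.params.gamma * N)


class TestK2Equivalences:
    @pytest.mark.parametrize("tau", [1.7, 2.0, 3.0])
    def test_n2_equals_chain_m3(self, tau):
        params = EpidemicParams(tau, 1.0)
        p_nb = solve_endemic(build_neighbourhood_n2(N, 2, params)).prevalence
        p_ch = solve_endemic(
            build_chain_motif_model(3, N, params).model).prevalence
        assert p_nb == pytest.approx(p_ch, abs=1e-6)

    @pytest.mark.parametrize("tau", [2.0, 3.0])
    def test_n3_equals_chain_m5(self, tau):
        params = EpidemicParams(tau, 1.0)
        p_nb = solve_endemic(build_neighbourhood_n3(N, 2, params)).prevalence
        p_ch = solve_endemic(
            build_chain_motif_model(5, N, params).model).prevalence
        assert p_nb == pytest.approx(p_ch, abs=1e-6)


class TestN3:
    def test_unsupported_degree_rejected(self, params11):
        with pytest.raises(ValueError):
            build_neighbourhood_n3(N, 4, params11)

    def test_zero_transmission_flows_to_all_susceptible_ball(self):
        model = build_neighbourhood_n3(N, 3, EpidemicParams(0.0, 1.0))
        t = np.linspace(0, 60, 7)
        _, Y = model.integrate(model.initial_state(0.3), t)
        dfe_idx = int(np.argmax(model.dfe_state))
        assert Y[-1][dfe_idx] == pytest.approx(N, rel=1e-6)

    def test_conservation(self, params11):
        model = build_neighbourhood_n3(N, 3, params11)
        t = np.linspace(0, 25, 6)
        _, Y = model.integrate(model.initial_state(1e-2), t)
        assert model.check_conservation(Y) < 1e-8
        assert Y.min() > -1e-6 * N

    def test_family_builder_orders(self, params11):
        assert build_neighbourhood_family(1, N, 3, params11).meta[
            "family"] == "meanfield"
        with pytest.raises(ValueError):
            build_neighbourhood_family(4, N, 3, params11)


class TestOrderingAgainstSimulation:
    def test_error_shrinks_with_order(self, params11, sim_prevalence_ref):
        sim_mean, sim_se = sim_prevalence_ref
        pw = solve_endemic(build_pairwise(N, 3, params11)).prevalence
        n2 = solve_endemic(build_neighbourhood_n2(N, 3, params11)).prevalence
        n3 = solve_endemic(build_neighbourhood_n3(N, 3, params11)).prevalence
        tol = 3 * sim_se
        assert abs(n3 - sim_mean) < abs(n2 - sim_mean) + tol
        assert abs(n2 - sim_mean) + tol < abs(pw - sim_mean)
        # approach from above: each order sits at or above the simulation
        assert pw > n2 > n3 > sim_mean - tol
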