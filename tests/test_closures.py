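import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sisnet import (EpidemicParams, build_meanfield, build_pairwise,
                    build_risk_structured_meanfield, critical_tau_ode,
                    fit_degree_distribution, growth_rate_jacobian,
                    growth_rate_ode, kirkwood_triple,
                    meanfield_endemic_prevalence, point_mass_spec,
                    relative_error, solve_endemic)

N = 10000.0


class TestMeanfield:
    def test_endemic_closed_form(self, params11):
        model = build_meanfield(N, 3, params11)
        res = solve_endemic(model)
        assert res.prevalence == pytest.approx(2.0 / 3.0, abs=1e-8)
        assert res.stable

    def test_subcritical_unique_disease_free_state(self):
        model = build_meanfield(N, 3, EpidemicParams(0.2, 1.0))
        assert solve_endemic(model).prevalence == 0.0

    def test_growth_rate_is_tau_k_minus_gamma(self, params11):
        model = build_meanfield(N, 3, params11)
        assert growth_rate_ode(model) == pytest.approx(2.0, rel=1e-5)
        assert growth_rate_jacobian(model) == pytest.approx(2.0, rel=1e-6)


class TestPairwise:
    def test_closure_arithmetic(self):
        # k=3, [SS]=6, [SI]=3, [S]=3 -> [SSI] = (2/3)*6*3/3 = 4
        assert kirkwood_triple(6.0, 3.0, 3.0, 3) == pytest.approx(4.0)
        assert kirkwood_triple(6.0, 3.0, 0.0, 3) == 0.0  # [B]=0 limit

    def test_critical_tau_is_gamma_over_k_minus_1(self):
        tc = critical_tau_ode(
            lambda t: build_pairwise(N, 3, EpidemicParams(t, 1.0)),
            bracket=(0.2, 1.0), tol=1e-4, method="growth")
        assert tc == pytest.approx(0.5, abs=2e-4)
        # marginal stability: prevalence at the threshold itself is ~0
        res = solve_endemic(build_pairwise(N, 3, EpidemicParams(0.5, 1.0)))
        assert res.prevalence <= 1e-4

    def test_endemic_agrees_with_independent_stiff_integration(self, params11):
        model = build_pairwise(N, 3, params11)
        res = solve_endemic(model)
        sol = solve_ivp(model.rhs_t, (0, 3000.0), model.initial_state(1e-3),
                        method="BDF", rtol=1e-12, atol=1e-8)
        prev_bdf = model.prevalence(sol.y[:, -1])
        assert res.prevalence == pytest.approx(prev_bdf, abs=1e-8)

    def test_equilibrium_bisection_on_endemic_existence(self):
        tc = critical_tau_ode(
            lambda t: build_pairwise(N, 3, EpidemicParams(t, 1.0)),
            bracket=(0.3, 1.0), tol=2e-3, method="equilibrium")
        assert tc == pytest.approx(0.5, abs=3e-3)


class TestRiskStructured:
    def test_point_mass_reduces_to_meanfield(self):
        params = EpidemicParams(2.0 / 3.0, 1.0)
        rs = build_risk_structured_meanfield(point_mass_spec(3), N, params)
        mf = build_meanfield(N, 3, params)
        t = np.linspace(0, 30, 31)
        _, Yrs = rs.integrate(rs.initial_state(1e-3), t)
        _, Ymf = mf.integrate(mf.initial_state(1e-3), t)
        I_rs = np.array([rs.prevalence(y) for y in Yrs])
        I_mf = np.array([mf.prevalence(y) for y in Ymf])
        np.testing.assert_allclose(I_rs, I_mf, atol=1e-7)
        assert solve_endemic(rs).prevalence == pytest.approx(0.5, abs=1e-8)

    def test_growth_rate_is_stub_weighted_closed_form(self):
        # proportionate mixing: invasion rate tau <k^2>/<k> - gamma, so
        # degree variance lowers the epidemic threshold
        params = EpidemicParams(2.0 / 3.0, 1.0)
        spec = fit_degree_distribution(3, 1.8, k_min=2)
        rs = build_risk_structured_meanfield(spec, N, params)
        k = spec.support
        p = spec.pmf
        expected = params.tau * float((k**2 * p).sum() / (k * p).sum()) - 1.0
        assert growth_rate_ode(rs) == pytest.approx(expected, rel=1e-5)
        assert expected > params.tau * 3 - 1.0  # above the point-mass rate


class TestGenericMachinery:
    def test_relative_error_examples(self):
        assert relative_error(0.5, 0.4) == pytest.approx(25.0)
        assert relative_error(0.37, 0.37) == 0.0
        assert relative_error(0.45, 0.36) == pytest.approx(25.0)
        with pytest.raises(ValueError):
            relative_error(0.5, 0.0)

    def test_zero_transmission_gives_disease_free(self, params11):
        model = build_pairwise(N, 3, EpidemicParams(0.0, 1.0))
        assert solve_endemic(model).prevalence == 0.0

    def test_meanfield_closed_form_helper(self, params11):
        assert meanfield_endemic_prevalence(3, params11) == \
            pytest.approx(2.0 / 3.0)
        assert meanfield_endemic_prevalence(3, EpidemicParams(0.2, 1.0)) == 0.0


class TestOrderingAgainstSimulation:
    def test_prevalence_hierarchy_meanfield_pairwise_simulation(
            self, params11, sim_prevalence_ref):
        sim_mean, sim_se = sim_prevalence_ref
        mf = solve_endemic(build_meanfield(N, 3, params11)).prevalence
        pw = solve_endemic(build_pairwise(N, 3, params11)).prevalence
        assert mf - pw > 3 * sim_se
        assert pw - sim_mean > 3 * sim_se
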