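import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sisnet import (EpidemicParams, MotifState, build_chain_motif_model,
                    build_k3_motif_model, build_meanfield, build_pairwise,
                    chain_dimension, chain_state_count, critical_tau_ode,
                    enumerate_chain_states, growth_rate_ode, solve_endemic)

N = 10000.0


class TestChainEnumeration:
    @pytest.mark.parametrize("m", list(range(1, 17)))
    def test_count_matches_closed_formula(self, m):
        states = enumerate_chain_states(m)
        assert len(states) == chain_state_count(m)
        assert len({s.canonical_form for s in states}) == len(states)

    def test_small_cases_explicit(self):
        assert {s.state_string for s in enumerate_chain_states(1)} == {"S", "I"}
        # the mixed pair's canonical representative is "IS" ("I" < "S")
        assert {s.state_string for s in enumerate_chain_states(2)} == \
            {"SS", "IS", "II"}
        assert chain_dimension(2) == 2

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="SI", min_size=1, max_size=12))
    def test_canonical_form_idempotent_and_reversal_invariant(self, s):
        a = MotifState("chain", s)
        b = MotifState("chain", s[::-1])
        assert a.canonical_form == b.canonical_form
        assert MotifState("chain", a.canonical_form).canonical_form == \
            a.canonical_form


class TestChainModelReductions:
    def test_m1_reproduces_meanfield_trajectory(self):
        params = EpidemicParams(2.0, 1.0)
        c1 = build_chain_motif_model(1, N, params).model
        mf = build_meanfield(N, 2, params)
        t = np.linspace(0, 25, 26)
        _, Y1 = c1.integrate(c1.initial_state(1e-3), t)
        _, Ym = mf.integrate(mf.initial_state(1e-3), t)
        p1 = [c1.prevalence(y) for y in Y1]
        pm = [mf.prevalence(y) for y in Ym]
        np.testing.assert_allclose(p1, pm, atol=1e-7)

    def test_m2_reproduces_pairwise_trajectory(self):
        params = EpidemicParams(2.0, 1.0)
        c2 = build_chain_motif_model(2, N, params).model
        pw = build_pairwise(N, 2, params)
        t = np.linspace(0, 25, 26)
        _, Y2 = c2.integrate(c2.initial_state(1e-3), t)
        _, Yp = pw.integrate(pw.initial_state(1e-3), t)
        p2 = [c2.prevalence(y) for y in Y2]
        pp = [pw.prevalence(y) for y in Yp]
        np.testing.assert_allclose(p2, pp, atol=1e-7)

    @pytest.mark.parametrize("tau", [1.7, 2.0, 3.0])
    def test_endemic_prevalence_monotone_in_order(self, tau):
        prev = [solve_endemic(
            build_chain_motif_model(m, N, EpidemicParams(tau, 1.0)).model
        ).prevalence for m in range(1, 9)]
        assert all(a >= b - 1e-9 for a, b in zip(prev, prev[1:]))
        assert prev[0] > prev[-1]

    def test_reflection_symmetry_preserved_along_trajectory(self):
        params = EpidemicParams(2.0, 1.0)
        model = build_chain_motif_model(4, N, params).model
        t = np.linspace(0, 15, 6)
        _, Y = model.integrate(model.initial_state(1e-2), t)
        rev = [int("".join(reversed(f"{b:04b}")), 2) for b in range(16)]
        for y in Y:
            np.testing.assert_allclose(y, y[rev], rtol=1e-7, atol=1e-7)
        # (m-1)-marginals taken at the two window offsets agree
        # (marginal consistency of the closure hierarchy); bit i of the
        # state index is window position i, so summing over the highest
        # bit drops position 3 and summing over the lowest drops position 0
        for y in Y:
            drop_last = y.reshape(2, 8).sum(axis=0)    # states of pos 0..2
            drop_first = y.reshape(8, 2).sum(axis=1)   # states of pos 1..3
            np.testing.assert_allclose(drop_last, drop_first,
                                       rtol=1e-7, atol=1e-7 * N)

    def test_conservation(self):
        params = EpidemicParams(2.0, 1.0)
        model = build_chain_motif_model(6, N, params).model
        t = np.linspace(0, 20, 11)
        _, Y = model.integrate(model.initial_state(1e-3), t)
        assert model.check_conservation(Y) < 1e-8


class TestChainThresholds:
    def test_meanfield_and_pairwise_limits(self):
        tc1 = critical_tau_ode(
            lambda t: build_chain_motif_model(1, N, EpidemicParams(t, 1.0)).model,
            bracket=(0.2, 1.0), tol=1e-4, method="growth")
        assert tc1 == pytest.approx(0.5, abs=2e-4)     # gamma/k, k=2
        tc2 = critical_tau_ode(
            lambda t: build_chain_motif_model(2, N, EpidemicParams(t, 1.0)).model,
            bracket=(0.5, 2.0), tol=1e-4, method="growth")
        assert tc2 == pytest.approx(1.0, abs=2e-4)     # gamma/(k-1)

    def test_thresholds_increase_toward_contact_process_value(self):
        tcs = [critical_tau_ode(
            lambda t, mm=m: build_chain_motif_model(mm, N,
                                                    EpidemicParams(t, 1.0)).model,
            bracket=(0.3, 1.64), tol=1e-3, method="growth")
            for m in (2, 4, 6)]
        assert tcs[0] < tcs[1] < tcs[2] < 1.6489


class TestK3Motifs:
    def test_unsupported_order_rejected(self, params11):
        with pytest.raises(ValueError):
            build_k3_motif_model(5, N, params11)

    def test_prevalence_interleaving_with_pairwise(self, params11):
        pw = solve_endemic(build_pairwise(N, 3, params11)).prevalence
        m3 = solve_endemic(build_k3_motif_model(3, N, params11).model
                           ).prevalence
        m4 = solve_endemic(build_k3_motif_model(4, N, params11).model
                           ).prevalence
        assert pw > m3 > m4

    def test_positivity_and_conservation(self, params11):
        for m in (3, 4):
            model = build_k3_motif_model(m, N, params11).model
            t = np.linspace(0, 25, 11)
            _, Y = model.integrate(model.initial_state(1e-3), t)
            assert Y.min() > -1e-6 * N
            assert model.check_conservation(Y) < 1e-8

    def test_critical_tau_increases_toward_simulated_value(self):
        tcs = []
        for m in (2, 3, 4):
            builder = (lambda t, mm=m:
                       build_pairwise(N, 3, EpidemicParams(t, 1.0)) if mm == 2
                       else build_k3_motif_model(mm, N,
                                                 EpidemicParams(t, 1.0)).model)
            tcs.append(critical_tau_ode(builder, bracket=(0.3, 0.6),
                                        tol=1e-3, method="growth"))
        assert tcs[0] < tcs[1] < tcs[2] < 0.56

    def test_growth_rates_decrease_with_order(self, params11):
        g_pw = growth_rate_ode(build_pairwise(N, 3, params11))
        g_m3 = growth_rate_ode(build_k3_motif_model(3, N, params11).model)
        g_m4 = growth_rate_ode(build_k3_motif_model(4, N, params11).model)
        assert g_pw > g_m3 > g_m4 > 0
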