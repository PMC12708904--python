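import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rumordyn as rd
from rumordyn.errors import ConfigurationError, InputError

rates = st.floats(min_value=0.0, max_value=2.0, allow_nan=False)
stocks = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)


class TestSIRDerivatives:
    def test_hand_evaluated_example(self):
        state = rd.SIRState(B=10, S=990, I=0, N=1000)
        params = rd.SIRParams(beta=0.3, delta=0.4, eta=0.5, lam=0.05, rho=0.0)
        dB, dS, dI = rd.sir_derivatives(state, params)
        assert dB == pytest.approx(0.47)
        assert dS == pytest.approx(-2.47)
        assert dI == pytest.approx(2.0)

    def test_no_believers_means_flow_only_between_s_and_i(self):
        state = rd.SIRState(B=0, S=700, I=300, N=1000)
        params = rd.SIRParams(beta=0.9, delta=0.5, eta=0.8, lam=0.1, rho=0.2)
        dB, dS, dI = rd.sir_derivatives(state, params)
        assert dB == 0.0
        assert dS == pytest.approx(params.rho * 300)
        assert dI == pytest.approx(-params.rho * 300)

    @given(b=stocks, s=stocks, i=stocks, beta=rates, delta=rates, lam=rates, rho=rates,
           eta=st.floats(min_value=0, max_value=1))
    def test_conservation_of_population(self, b, s, i, beta, delta, eta, lam, rho):
        n = b + s + i
        if n <= 0:
            return
        state = rd.SIRState(B=b, S=s, I=i, N=n)
        params = rd.SIRParams(beta=beta, delta=delta, eta=eta, lam=lam, rho=rho)
        dB, dS, dI = rd.sir_derivatives(state, params)
        assert abs(dB + dS + dI) <= 1e-12 * max(n, 1.0)

    def test_invalid_population_rejected(self):
        with pytest.raises(InputError):
            rd.SIRState(B=1, S=1, I=1, N=0)
        with pytest.raises(InputError):
            rd.SIRState(B=5, S=5, I=5, N=100)  # stocks do not sum to N


class TestIntegrateSIR:
    def test_zero_parameters_give_constant_trajectory(self):
        state = rd.SIRState(B=10, S=80, I=10, N=100)
        traj = rd.integrate_sir(state, rd.SIRParams(0, 0, 0, 0, 0), np.linspace(0, 10, 101))
        for col, v0 in [("B", 10), ("S", 80), ("I", 10)]:
            assert np.allclose(traj[col], v0)

    @pytest.mark.parametrize("method", ["rk4", "adaptive"])
    def test_linear_decay_matches_closed_form(self, method):
        """With transmission off, believers decay exponentially at rate
        delta*eta + lam."""
        state = rd.SIRState(B=100, S=800, I=100, N=1000)
        params = rd.SIRParams(beta=0.0, delta=0.4, eta=0.5, lam=0.05, rho=0.0)
        t = np.linspace(0, 5, 51)
        traj = rd.integrate_sir(state, params, t, method=method)
        expected = 100 * np.exp(-(0.4 * 0.5 + 0.05) * 5)
        assert traj["B"][-1] == pytest.approx(expected, rel=1e-4)

    def test_rk4_and_adaptive_agree(self):
        state = rd.SIRState(B=10, S=990, I=0, N=1000)
        params = rd.SIRParams(beta=0.3, delta=0.4, eta=0.5, lam=0.05, rho=0.0)
        t = np.linspace(0, 30, 301)
        b1 = rd.integrate_sir(state, params, t, method="rk4")["B"]
        b2 = rd.integrate_sir(state, params, t, method="adaptive")["B"]
        assert np.max(np.abs(b1 - b2)) < 1e-3 * state.N

    def test_conservation_along_trajectory(self):
        state = rd.SIRState(B=50, S=900, I=50, N=1000)
        params = rd.SIRParams(beta=0.8, delta=0.3, eta=0.6, lam=0.1, rho=0.05)
        traj = rd.integrate_sir(state, params, np.linspace(0, 40, 401))
        total = traj["B"] + traj["S"] + traj["I"]
        assert np.max(np.abs(total - 1000)) < 1e-6 * 1000


class TestTrustRumorModel:
    def test_fixed_point_at_full_trust_no_rumor(self):
        dT, dR = rd.trust_rumor_derivatives(rd.TrustRumorState(T=1.0, R=0.0), rd.TrustRumorParams())
        assert dT == 0.0 and dR == 0.0

    def test_hand_evaluated_example(self):
        params = rd.TrustRumorParams(alpha_T=0.2, beta_T=0.4, gamma_T=0.5,
                                     delta_R=0.1, eps_R=0.3, zeta_R=0.2, E_fn=lambda t: 0.5)
        dT, dR = rd.trust_rumor_derivatives(rd.TrustRumorState(T=0.6, R=0.3), params)
        assert dT == pytest.approx(0.19)
        assert dR == pytest.approx(-0.111)

    @given(T=st.floats(0, 2), R=st.floats(0, 5), a=rates, b=rates, g=rates,
           d=rates, e=rates, z=rates, E=st.floats(0, 1))
    def test_rumor_derivative_never_positive(self, T, R, a, b, g, d, e, z, E):
        params = rd.TrustRumorParams(a, b, g, d, e, z, E_fn=lambda t: E)
        _, dR = rd.trust_rumor_derivatives(rd.TrustRumorState(T=T, R=R), params)
        assert dR <= 0.0

    def test_negative_forcing_rejected(self):
        params = rd.TrustRumorParams(E_fn=lambda t: -0.1)
        with pytest.raises(InputError):
            rd.trust_rumor_derivatives(rd.TrustRumorState(T=0.5, R=0.1), params)

    def test_trust_equilibrium_with_no_rumor(self):
        """With R0 = 0, trust relaxes to T* = 1 + beta_T E / alpha_T."""
        params = rd.TrustRumorParams(alpha_T=0.5, beta_T=0.2, E_fn=lambda t: 1.0)
        traj = rd.integrate_trust_rumor(
            rd.TrustRumorState(T=0.3, R=0.0), params, np.linspace(0, 40, 401)
        )
        assert np.allclose(traj["R"], 0.0)
        assert traj["T"][-1] == pytest.approx(1 + 0.2 * 1.0 / 0.5, rel=1e-4)

    def test_pure_decay_matches_closed_form(self):
        params = rd.TrustRumorParams(alpha_T=0, beta_T=0, gamma_T=0, delta_R=0.2, eps_R=0, zeta_R=0)
        traj = rd.integrate_trust_rumor(
            rd.TrustRumorState(T=0.5, R=0.5), params, np.linspace(0, 5, 51)
        )
        assert traj["R"][-1] == pytest.approx(0.5 * np.exp(-1.0), abs=1e-4)

    def test_all_zero_parameters_give_constant_trajectory(self):
        params = rd.TrustRumorParams(0, 0, 0, 0, 0, 0)
        traj = rd.integrate_trust_rumor(rd.TrustRumorState(T=0.7, R=0.2), params, np.linspace(0, 10, 101))
        assert np.allclose(traj["T"], 0.7) and np.allclose(traj["R"], 0.2)

    def test_rumor_monotone_nonincreasing(self):
        params = rd.TrustRumorParams(E_fn=lambda t: 0.3)
        traj = rd.integrate_trust_rumor(
            rd.TrustRumorState(T=0.2, R=0.8), params, np.linspace(0, 20, 201)
        )
        assert np.all(np.diff(traj["R"]) <= 1e-12)

    @pytest.mark.parametrize("zeta_pair", [(0.0, 0.2), (0.2, 0.5), (0.5, 1.5)])
    def test_stronger_trust_suppression_never_raises_rumor(self, zeta_pair):
        lo, hi = zeta_pair
        t = np.linspace(0, 15, 151)
        state = rd.TrustRumorState(T=0.6, R=0.5)
        r_lo = rd.integrate_trust_rumor(state, rd.TrustRumorParams(zeta_R=lo, E_fn=lambda t: 0.2), t)["R"]
        r_hi = rd.integrate_trust_rumor(state, rd.TrustRumorParams(zeta_R=hi, E_fn=lambda t: 0.2), t)["R"]
        assert np.all(r_hi <= r_lo + 1e-12)


@pytest.fixture(scope="module")
def trajectories():
    return rd.run_scenarios(rd.ScenarioEngineConfig())


class TestScenarioEngine:

    def test_baseline_runs_first_and_is_reproducible(self, trajectories):
        assert next(iter(trajectories)) == "baseline"
        again = rd.run_scenarios(rd.ScenarioEngineConfig())
        assert np.array_equal(trajectories["baseline"]["believers"], again["baseline"]["believers"])

    def test_every_intervention_suppresses_believers_at_all_times(self, trajectories):
        base = trajectories["baseline"]["believers"]
        for name in ("trust_enhancement", "panic_reduction", "strengthened_debunking"):
            assert np.all(trajectories[name]["believers"] <= base * (1 + 1e-9)), name

    def test_comprehensive_is_strongest_everywhere(self, trajectories):
        comp = trajectories["comprehensive"]["believers"]
        for name in ("baseline", "trust_enhancement", "panic_reduction", "strengthened_debunking"):
            assert np.all(comp <= trajectories[name]["believers"] * (1 + 1e-9)), name

    def test_debunking_alone_is_the_weakest_single_intervention(self, trajectories):
        finals = {n: trajectories[n]["believers"][-1]
                  for n in ("trust_enhancement", "panic_reduction", "strengthened_debunking")}
        assert finals["strengthened_debunking"] == max(finals.values())
        assert finals["strengthened_debunking"] >= trajectories["comprehensive"]["believers"][-1]

    def test_panic_rises_and_approaches_a_plateau(self, trajectories):
        for name, traj in trajectories.items():
            panic = traj["panic"]
            assert panic[-1] > panic[0], name
            assert np.isfinite(panic).all()
            # near-zero slope over the last tenth of the horizon
            tail_change = abs(panic[-1] - panic[-len(panic) // 10])
            assert tail_change < 0.15 * (panic.max() - panic.min()), name

    def test_trust_enhancement_trust_rises_then_declines(self, trajectories):
        trust = trajectories["trust_enhancement"]["trust"]
        assert trust.argmax() > 0
        assert trust[-1] < trust.max() - 0.01

    def test_population_conserved_in_every_scenario(self, trajectories):
        n = rd.ScenarioEngineConfig().N
        for traj in trajectories.values():
            total = traj["believers"] + traj["susceptibles"] + traj["immune"]
            assert np.max(np.abs(total - n)) < 1e-6 * n

    def test_baseline_versus_itself_is_identical(self):
        cfg = rd.ScenarioEngineConfig()
        a = rd.run_scenarios(cfg, [rd.ScenarioSpec("baseline")])
        b = rd.run_scenarios(cfg, [rd.ScenarioSpec("baseline")])
        assert np.array_equal(a["baseline"]["believers"], b["baseline"]["believers"])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ConfigurationError):
            rd.run_scenarios(
                rd.ScenarioEngineConfig(),
                [rd.ScenarioSpec("x", trust_multiplier=1.1), rd.ScenarioSpec("x", panic_multiplier=0.9)],
            )

    def test_missing_baseline_is_prepended(self):
        out = rd.run_scenarios(rd.ScenarioEngineConfig(), [rd.ScenarioSpec("only", trust_multiplier=1.2)])
        assert list(out) == ["baseline", "only"]

    def test_literacy_stock_accumulates_towards_one(self):
        cfg = rd.ScenarioEngineConfig(horizon=80.0)
        out = rd.run_scenarios(cfg, [rd.ScenarioSpec("lit", trust_multiplier=1.01, literacy_enabled=True)])
        lit = out["lit"]["literacy"]
        assert np.all(np.diff(lit) > 0)
        assert lit[0] == pytest.approx(cfg.H0)
        assert lit[-1] > 0.9
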