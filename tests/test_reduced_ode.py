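"""Cascade right-hand side, stiff integration, scenarios and oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from clotfilm import (
    Scenario,
    apply_scenario,
    default_parameters,
    equilibrium_free_fraction,
    pathway_decomposition,
    rhs,
    simulate,
)
from clotfilm.reduced_ode import STATE_NAMES, SolverError

LN2 = math.log(2)


class TestRhs:
    def test_initial_state_derivative(self, params):
        """Direct substitution of the initial condition into the printed
        equations: only TF* decay and the two TF*-driven activations fire."""
        tf0 = 2.2e-6
        y = np.array([tf0, 0, 0, 0, 0, 0, 0, 0])
        d = rhs(0.0, y, params)
        a1 = params.reaction(1).alpha
        a2 = params.reaction(2).alpha
        assert d[STATE_NAMES.index("tf_star")] == pytest.approx(-params.k_i_tf * tf0)
        assert d[STATE_NAMES.index("xa")] == pytest.approx(a1 * tf0, rel=1e-12)
        assert d[STATE_NAMES.index("ixa")] == pytest.approx(a2 * tf0, rel=1e-12)
        assert np.all(d[3:] == 0.0)

    def test_zero_state_is_fixed_point(self, params):
        assert np.all(rhs(0.0, np.zeros(8), params) == 0.0)

    def test_no_sites_limit(self, params):
        """With fibrin = 0 any E-site occupancy can only unbind."""
        y = np.zeros(8)
        y[STATE_NAMES.index("iia_free")] = 0.05
        y[STATE_NAMES.index("es")] = 0.01
        d = rhs(0.0, y, params)
        des = d[STATE_NAMES.index("es")]
        expected = -params.site_e.kr * 0.01 - params.site_e.kf * 0.05 * 0.01
        assert des == pytest.approx(expected, rel=1e-12)
        assert des < 0

    def test_rejects_non_finite_state(self, params):
        y = np.zeros(8)
        y[0] = float("nan")
        with pytest.raises(SolverError):
            rhs(0.0, y, params)


class TestSimulate:
    def test_trajectory_invariants(self, baseline_traj):
        t = baseline_traj
        assert np.all(np.diff(t.times) > 0)
        assert t.states.min() >= 0.0
        e_cap = t.params.site_e.sites_per_monomer * t.fibrin
        g_cap = t.params.site_gamma.sites_per_monomer * t.fibrin
        assert np.all(t.es <= e_cap + 1e-9)
        assert np.all(t.gs <= g_cap + 1e-9)

    def test_thrombin_budget_closes(self, baseline_traj):
        """Cumulative production ∫η4·α4·Xa dt equals retained thrombin plus
        cumulative elution/inhibition losses (within quadrature error)."""
        t = baseline_traj
        prod = np.trapezoid(t.params.reaction(4).rate * t.xa, t.times)
        loss = np.trapezoid((t.params.k_elute + t.params.k_i) * t.iia_free, t.times)
        assert prod == pytest.approx(t.total_thrombin[-1] + loss, rel=5e-3)

    def test_quasi_steady_fxia(self, baseline_traj):
        """After 600 s FXIa tracks its source/sink balance
        η6·α6·IIa_free/(k_elute + k_i)."""
        t = baseline_traj
        m = t.times >= 600
        qs = (t.params.reaction(6).rate * t.iia_free[m]
              / (t.params.k_elute + t.params.k_i))
        assert np.max(np.abs(qs - t.xia[m]) / t.xia[m]) < 0.05

    def test_solver_tolerance_robustness(self, baseline_traj):
        tight = simulate(rtol=5e-9, atol=5e-13)
        for name in ("xa", "ixa", "xia", "fibrin", "iia_free"):
            a, b = baseline_traj[name][-1], tight[name][-1]
            assert abs(a - b) <= 1e-3 * max(abs(b), 1e-12)

    def test_free_thrombin_washout_halflife(self, params):
        """With production off and fibrin generation blocked, free thrombin
        decays first order with half-life ln2/(k_elute + k_i) ≈ 1.936 s."""
        p = params.replace_reaction(5, kcat=0.0)  # no fibrin → no binding sink
        y0 = np.zeros(8)
        y0[STATE_NAMES.index("iia_free")] = 0.1
        sol = solve_ivp(lambda t, y: rhs(t, y, p), (0, 10), y0,
                        method="BDF", rtol=1e-10, atol=1e-14,
                        t_eval=np.linspace(0, 10, 2001))
        c = sol.y[STATE_NAMES.index("iia_free")]
        t_half = np.interp(0.05, c[::-1], sol.t[::-1])
        assert t_half == pytest.approx(LN2 / (params.k_elute + params.k_i),
                                       rel=1e-3)

    def test_rejects_nonpositive_horizon(self):
        with pytest.raises(ValueError):
            simulate(t_end=0.0)


class TestApplyScenario:
    def test_escape_halflife_sets_k_elute(self, params):
        p = apply_scenario(params, Scenario(escape_halflife=2.0))
        assert p.k_elute == pytest.approx(0.34657, rel=1e-4)
        p4 = apply_scenario(params, Scenario(escape_halflife=4.0))
        assert p4.k_elute == pytest.approx(LN2 / 4)

    def test_gamma_prime_scaling(self, params):
        p = apply_scenario(params, Scenario(gamma_prime_scale=2.0))
        assert p.site_gamma.sites_per_monomer == pytest.approx(0.6)
        assert p.site_e.sites_per_monomer == 1.6

    def test_hemophilia_zeroes_both_tenase_paths(self, params):
        p = apply_scenario(params, Scenario(hemophilia=True))
        assert p.reaction(2).alpha == 0.0
        assert p.reaction(3).alpha == 0.0
        assert p.reaction(1).alpha > 0

    def test_gprp_alpha5_zero_gives_no_fibrin(self):
        traj = simulate(scenario=Scenario(gprp=True), t_end=100.0)
        assert np.all(traj.fibrin == 0.0)
        assert np.all(traj.es == 0.0)

    def test_gprp_kd_inf_keeps_kr_consistency(self, params):
        p = apply_scenario(params, Scenario(gprp=True, gprp_mode="kd_inf"))
        for site in p.sites:
            assert site.Kd == 1e7
            assert site.kr == pytest.approx(site.kf * site.Kd, rel=1e-12)

    def test_escape_time_monotonicity(self, escape_sweep):
        """Thrombin and fibrin at 800 s increase with the escape half-life."""
        totals = [escape_sweep[tau].total_thrombin[-1] for tau in (1.0, 2.0, 4.0)]
        fibrins = [escape_sweep[tau].fibrin[-1] for tau in (1.0, 2.0, 4.0)]
        assert totals[0] < totals[1] < totals[2]
        assert fibrins[0] < fibrins[1] < fibrins[2]

    def test_invalid_scenario_rejected(self):
        with pytest.raises(Exception):
            Scenario(gamma_prime_scale=0.0)
        with pytest.raises(Exception):
            Scenario(gprp_mode="bogus")


class TestGammaPrimeLevels:
    def test_more_gamma_sites_sequester_more_thrombin(self):
        """Doubling γ′-fibrinogen lowers free thrombin and fibrin; halving
        raises both (site capacity competes with the fluid phase)."""
        runs = {s: simulate(scenario=Scenario(gamma_prime_scale=s))
                for s in (0.5, 1.0, 2.0)}
        free = {s: runs[s].iia_free[-1] for s in runs}
        fib = {s: runs[s].fibrin[-1] for s in runs}
        assert free[2.0] < free[1.0] < free[0.5]
        assert fib[2.0] < fib[1.0] < fib[0.5]


@pytest.fixture(scope="module")
def decomposition():
    return pathway_decomposition(t_end=800.0)


class TestPathwayDecomposition:
    def test_no_feedback_removes_fxia(self, decomposition):
        assert np.all(decomposition.no_fxia_feedback.xia == 0.0)

    def test_feedback_negligible_early(self, decomposition):
        d = decomposition
        m = (d.baseline.times > 0) & (d.baseline.times < 100)
        frac = d.fxia_pathway("ixa")[m] / np.maximum(d.baseline.ixa[m], 1e-300)
        assert np.max(frac) < 0.15

    def test_feedback_dominates_late_tenase(self, decomposition):
        d = decomposition
        m = d.baseline.times >= 500
        assert np.all(d.fxia_pathway("ixa")[m] > d.no_fxia_feedback.ixa[m])

    def test_hemophilia_makes_little_prothrombinase(self, decomposition):
        d = decomposition
        assert d.hemophilia.xa[-1] < 0.05 * d.baseline.xa[-1]


class TestEquilibriumFreeFraction:
    def test_no_fibrin_is_all_free(self, params):
        assert equilibrium_free_fraction(1.0, 0.0, params.sites) == 1.0

    def test_dilute_limit_closed_form(self, params):
        """1/(1 + θ_E/K_E + θ_γ/K_γ) at 90 μM fibrin."""
        expected = 1.0 / (1.0 + 1.6 * 90 / 2.8 + 0.3 * 90 / 0.1)
        got = equilibrium_free_fraction(1e-9, 90.0, params.sites)
        assert got == pytest.approx(expected, rel=1e-6)
        assert got == pytest.approx(0.00310, abs=5e-6)

    def test_weak_sites_release_everything(self, params):
        weak = (params.site_e.with_overrides(Kd=1e12),
                params.site_gamma.with_overrides(Kd=1e12))
        assert equilibrium_free_fraction(1.0, 90.0, weak) == pytest.approx(1.0, rel=1e-4)

    @given(total=st.floats(1e-6, 100.0), fibrin=st.floats(0.0, 500.0))
    def test_fraction_in_unit_interval(self, total, fibrin):
        f = equilibrium_free_fraction(total, fibrin, default_parameters().sites)
        assert 0.0 < f <= 1.0 + 1e-12

    @given(total=st.floats(1e-3, 10.0))
    def test_monotone_decreasing_in_fibrin(self, total):
        sites = default_parameters().sites
        fracs = [equilibrium_free_fraction(total, fib, sites)
                 for fib in (0.0, 9.0, 30.0, 90.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_kinetic_limit_matches_equilibrium(self, params, baseline_traj):
        """Scaling k_f (at fixed K_D) ×100 leaves totals unchanged within 1%
        and drives the kinetic partition onto the equilibrium curve."""
        p = params.replace_site("E", kf=1e4).replace_site("gamma_prime", kf=1e4)
        fast = simulate(p)
        assert fast.total_thrombin[-1] == pytest.approx(
            baseline_traj.total_thrombin[-1], rel=0.01)
        assert fast.fibrin[-1] == pytest.approx(baseline_traj.fibrin[-1], rel=0.01)
        s = fast.at(800.0)
        eq = equilibrium_free_fraction(s.total_thrombin, s.fibrin, params.sites)
        assert s.iia_free / s.total_thrombin == pytest.approx(eq, rel=0.01)
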