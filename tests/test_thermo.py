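"""Closed-form thermodynamics: Gibbs-Helmholtz, error propagation,
dCp fitting, multistate sums, van't Hoff binding, populations and
thermograms."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

import foldtherm as ft
from foldtherm import thermo
from foldtherm.thermo import R

from conftest import exact_dg_transition


# -- Gibbs-Helmholtz -------------------------------------------------------

class TestGibbsHelmholtz:
    def test_flavodoxin_fi_step_at_25C(self, fi_transition):
        # printed experimental parameters give dG = 1.1 kcal/mol
        assert ft.gibbs_helmholtz(fi_transition, 298.15) == pytest.approx(
            1.1, abs=0.05)

    def test_vanishes_at_tm(self, fi_transition):
        assert ft.gibbs_helmholtz(fi_transition, fi_transition.Tm) == 0.0

    def test_zero_dcp_reduces_to_enthalpic_term(self):
        t = ft.TransitionThermo(dH_Tm=100.0, dCp=0.0, Tm=350.0)
        # dH * (1 - T/Tm) evaluated directly
        assert ft.gibbs_helmholtz(t, 298.15) == pytest.approx(
            14.8143, abs=1e-4)

    def test_vectorised_grid(self, fi_transition):
        grid = np.array([290.0, 316.2, 330.0])
        dg = ft.gibbs_helmholtz(fi_transition, grid)
        assert dg.shape == (3,)
        assert dg[1] == pytest.approx(0.0, abs=1e-12)

    def test_rejects_nonpositive_temperature(self, fi_transition):
        with pytest.raises(ValueError):
            ft.gibbs_helmholtz(fi_transition, 0.0)
        with pytest.raises(ValueError):
            ft.TransitionThermo(dH_Tm=10.0, dCp=1.0, Tm=-5.0)

    @given(dh=st.floats(1.0, 200.0), dcp=st.floats(0.0, 5.0),
           tm=st.floats(280.0, 400.0))
    def test_zero_at_tm_for_all_parameters(self, dh, dcp, tm):
        t = ft.TransitionThermo(dH_Tm=dh, dCp=dcp, Tm=tm)
        assert abs(ft.gibbs_helmholtz(t, tm)) < 1e-9

    @given(dh=st.floats(5.0, 150.0), dcp=st.floats(0.0, 4.0),
           tm=st.floats(300.0, 380.0))
    def test_slope_at_tm_is_vant_hoff(self, dh, dcp, tm):
        # ddG/dT at Tm = -dH_Tm / Tm
        t = ft.TransitionThermo(dH_Tm=dh, dCp=dcp, Tm=tm)
        h = 1e-4
        num = (ft.gibbs_helmholtz(t, tm + h)
               - ft.gibbs_helmholtz(t, tm - h)) / (2 * h)
        assert num == pytest.approx(-dh / tm, rel=1e-5, abs=1e-7)


class TestErrorPropagation:
    def test_zero_ses_give_zero(self):
        t = ft.TransitionThermo(dH_Tm=50.0, dCp=1.0, Tm=330.0)
        assert ft.propagate_gh_error(t, 298.15) == 0.0

    def test_matches_finite_difference_partials(self, fi_transition):
        t = fi_transition
        T = 298.15
        h = 1e-6
        parts = []
        for field, se in (("dH_Tm", t.se_dH), ("dCp", t.se_dCp),
                          ("Tm", t.se_Tm)):
            lo = {f: getattr(t, f) for f in ("dH_Tm", "dCp", "Tm")}
            hi = dict(lo)
            lo[field] -= h
            hi[field] += h
            g_hi = ft.gibbs_helmholtz(ft.TransitionThermo(**hi), T)
            g_lo = ft.gibbs_helmholtz(ft.TransitionThermo(**lo), T)
            parts.append(((g_hi - g_lo) / (2 * h)) * se)
        expected = math.sqrt(sum(p**2 for p in parts))
        assert ft.propagate_gh_error(t, T) == pytest.approx(expected, abs=1e-6)

    def test_delta_method_is_linear_in_ses(self):
        t1 = ft.TransitionThermo(32.0, 1.35, 316.2, se_dH=1.1, se_dCp=0.3,
                                 se_Tm=0.2)
        t2 = ft.TransitionThermo(32.0, 1.35, 316.2, se_dH=2.2, se_dCp=0.6,
                                 se_Tm=0.4)
        assert ft.propagate_gh_error(t2, 298.15) == pytest.approx(
            2.0 * ft.propagate_gh_error(t1, 298.15), rel=1e-12)


# -- dCp fitting -----------------------------------------------------------

class TestFitDcp:
    def test_exact_line(self):
        fit = ft.fit_dcp([(300.0, 50.0), (310.0, 60.0), (320.0, 70.0)])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(-250.0)
        assert fit.se_slope == pytest.approx(0.0, abs=1e-10)

    def test_two_points_flagged_exact(self):
        fit = ft.fit_dcp([(300.0, 50.0), (320.0, 70.0)])
        assert fit.slope == pytest.approx(1.0)
        assert fit.exact_fit
        assert fit.se_slope == 0.0

    def test_noisy_recovery_against_normal_equations(self):
        rng = np.random.default_rng(42)
        T = np.array([310.0, 320.0, 330.0])
        dH = 10.0 + 1.5 * T + rng.normal(0, 2.0, 3)
        fit = ft.fit_dcp(np.column_stack([T, dH]))
        # independent OLS oracle via the normal equations
        sxx = np.sum((T - T.mean()) ** 2)
        slope = np.sum((T - T.mean()) * (dH - dH.mean())) / sxx
        intercept = dH.mean() - slope * T.mean()
        resid = dH - (intercept + slope * T)
        s2 = np.sum(resid**2) / (len(T) - 2)
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)
        assert fit.se_slope == pytest.approx(math.sqrt(s2 / sxx), rel=1e-9)
        assert abs(fit.slope - 1.5) < 3 * fit.se_slope

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            ft.fit_dcp([(300.0, 50.0)])
        with pytest.raises(ValueError):
            ft.fit_dcp([(300.0, 50.0), (300.0, 60.0)])


class TestExtrapolateDh:
    def test_line_evaluation(self):
        fit = ft.fit_dcp([(300.0, 50.0), (310.0, 60.0), (320.0, 70.0)])
        value, se = ft.extrapolate_dh(fit, 330.0)
        assert value == pytest.approx(80.0)
        value, _ = ft.extrapolate_dh(fit, 340.0)
        assert value == pytest.approx(90.0)

    def test_reproduces_fitted_point(self):
        fit = ft.fit_dcp([(300.0, 50.0), (310.0, 60.0), (320.0, 70.0)])
        value, _ = ft.extrapolate_dh(fit, 310.0)
        assert value == pytest.approx(fit.predict(310.0))

    def test_prediction_se_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        T = np.array([300.0, 310.0, 320.0, 330.0])
        dH = 5.0 + 1.2 * T + rng.normal(0, 3.0, 4)
        fit = ft.fit_dcp(np.column_stack([T, dH]))
        x0 = 345.0
        slope = fit.slope
        resid = dH - fit.predict(T)
        s2 = np.sum(resid**2) / (len(T) - 2)
        sxx = np.sum((T - T.mean()) ** 2)
        expected = math.sqrt(s2 * (1 / len(T) + (x0 - T.mean()) ** 2 / sxx))
        _, se = ft.extrapolate_dh(fit, x0)
        assert se == pytest.approx(expected, rel=1e-9)


# -- multistate sums and differences --------------------------------------

class TestAdditivity:
    def test_global_stability_is_sum_of_steps(self):
        # calculated flavodoxin steps: 1.3 + 3.0 -> 4.3
        m = ft.MultiStateModel([
            exact_dg_transition(1.3, label="F-to-I"),
            exact_dg_transition(3.0, label="I-to-U"),
        ])
        per, (total, _) = ft.multistate_dG(m, 298.15)
        assert [v for v, _ in per] == pytest.approx([1.3, 3.0])
        assert total == pytest.approx(4.3)

    def test_experimental_steps_sum(self):
        m = ft.MultiStateModel([
            exact_dg_transition(1.1, label="F-to-I"),
            exact_dg_transition(2.9, label="I-to-U"),
        ])
        _, (total, _) = ft.multistate_dG(m, 298.15)
        assert total == pytest.approx(4.0)

    def test_single_transition_is_identity(self, fi_transition):
        m = ft.MultiStateModel([fi_transition])
        per, (total, se) = ft.multistate_dG(m, 300.0)
        assert total == per[0][0]
        assert se == per[0][1]

    def test_se_modes(self):
        m = ft.MultiStateModel([
            exact_dg_transition(1.3, label="F-to-I", se_dH=2.0),
            exact_dg_transition(3.0, label="I-to-U", se_dH=4.0),
        ])
        # dG = dH/2 at T, so se(dG) = se_dH/2: 1.0 and 2.0
        _, (_, se_q) = ft.multistate_dG(m, 298.15, se_mode="quadrature")
        _, (_, se_s) = ft.multistate_dG(m, 298.15, se_mode="sum")
        assert se_q == pytest.approx(math.hypot(1.0, 2.0))
        assert se_s == pytest.approx(3.0)
        assert se_s >= se_q

    def test_additive_dcp(self):
        m = ft.MultiStateModel([
            ft.TransitionThermo(35.6, 1.5, 316.2, se_dCp=0.1, label="F-to-I"),
            ft.TransitionThermo(48.1, 1.0, 330.0, se_dCp=0.0, label="I-to-U"),
        ])
        total, _ = ft.additive_dcp(m)
        assert total == pytest.approx(2.5)
        m_exp = ft.MultiStateModel([
            ft.TransitionThermo(32.0, 1.35, 316.2, label="F-to-I"),
            ft.TransitionThermo(55.6, 1.55, 330.0, label="I-to-U"),
        ])
        assert ft.additive_dcp(m_exp)[0] == pytest.approx(2.9)

    def test_ddg(self):
        # CI2 Ile76Ala vs WT and pH 6.3 vs 3.0 stability differences
        value, se = ft.ddg(1.0, 4.3, se_b=0.2, se_a=0.4)
        assert value == pytest.approx(-3.3)
        assert se == pytest.approx(math.hypot(0.2, 0.4))
        assert ft.ddg(7.2, 5.4)[0] == pytest.approx(1.8)
        assert ft.ddg(2.0, 2.0)[0] == 0.0

    def test_holo_dcp_estimate(self):
        value, se = ft.holo_dcp_estimate(2.9, -0.6, se_dcp_apo=0.6,
                                         se_dcp_bind=0.02)
        assert value == pytest.approx(3.5)
        assert se == pytest.approx(math.hypot(0.6, 0.02))
        assert ft.holo_dcp_estimate(2.9, 0.0)[0] == pytest.approx(2.9)
        # estimate(a, b) - a == -b
        assert ft.holo_dcp_estimate(1.7, 0.3)[0] - 1.7 == pytest.approx(-0.3)


# -- van't Hoff binding ----------------------------------------------------

class TestVantHoff:
    def test_identity_at_reference(self):
        b = ft.BindingModel(Kb0=3.61e9, dH_bind=-11.0, dCp_bind=-0.6)
        assert ft.vant_hoff_kb(b, b.T0) == pytest.approx(b.Kb0, rel=1e-12)

    def test_athermal_binding_is_constant(self):
        b = ft.BindingModel(Kb0=1e6, dH_bind=0.0, dCp_bind=0.0)
        for T in (280.0, 298.15, 350.0):
            assert ft.vant_hoff_kb(b, T) == pytest.approx(1e6, rel=1e-12)

    def test_constant_dh_closed_form(self):
        b = ft.BindingModel(Kb0=1e9, dH_bind=-11.0, dCp_bind=0.0)
        expected = 1e9 * math.exp(-(-11.0) / R * (1 / 308.15 - 1 / 298.15))
        assert ft.vant_hoff_kb(b, 308.15) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("dcp_bind", [0.0, -0.6])
    def test_matches_numeric_integration(self, dcp_bind):
        # oracle: integrate d lnK/dT = dH(T)/(R T^2) numerically
        b = ft.BindingModel(Kb0=1e9, dH_bind=-11.0, dCp_bind=dcp_bind)
        for T in (285.0, 310.0, 330.0):
            integral, _ = quad(
                lambda x: (b.dH_bind + b.dCp_bind * (x - b.T0)) / (R * x**2),
                b.T0, T)
            expected = b.Kb0 * math.exp(integral)
            assert ft.vant_hoff_kb(b, T) == pytest.approx(expected, rel=1e-6)


class TestHoloStability:
    @pytest.fixture
    def apo(self):
        return ft.MultiStateModel([exact_dg_transition(4.3)])

    @pytest.fixture
    def binding(self):
        return ft.BindingModel(Kb0=3.61e9, dH_bind=-11.0, dCp_bind=-0.6,
                               ligand_conc=1.0)

    def test_standard_state_flavodoxin(self, apo, binding):
        dg, _ = ft.holo_stability(apo, binding, 298.15)
        assert dg == pytest.approx(17.3, abs=0.05)

    def test_reduces_to_apo_without_ligand(self, apo, binding):
        b0 = ft.BindingModel(Kb0=binding.Kb0, dH_bind=binding.dH_bind,
                             dCp_bind=binding.dCp_bind, ligand_conc=0.0)
        for T in (280.0, 298.15, 310.0):
            dg, _ = ft.holo_stability(apo, b0, T, warn_unreliable=False)
            _, (dg_apo, _) = ft.multistate_dG(apo, T)
            assert dg == pytest.approx(dg_apo, rel=1e-12)

    def test_half_saturation_adds_rtln2(self, apo):
        b = ft.BindingModel(Kb0=1.0, dH_bind=0.0, dCp_bind=0.0,
                            ligand_conc=1.0)
        dg, _ = ft.holo_stability(apo, b, 298.15)
        assert dg - 4.3 == pytest.approx(R * 298.15 * math.log(2), rel=1e-9)
        assert dg - 4.3 == pytest.approx(0.4107, abs=5e-4)

    def test_saturating_approximation(self, apo, binding):
        exact, _ = ft.holo_stability(apo, binding, 298.15)
        approx, _ = ft.holo_stability(apo, binding, 298.15,
                                      saturating_approx=True)
        # Kb*[L] ~ 3.6e9 so ln(1+x) ~ ln(x)
        assert approx == pytest.approx(exact, abs=1e-6)

    def test_unreliable_above_first_apo_tm(self, binding):
        apo = ft.MultiStateModel([
            ft.TransitionThermo(32.0, 1.35, 316.2, label="F-to-I"),
            ft.TransitionThermo(55.6, 1.55, 330.0, label="I-to-U"),
        ])
        with pytest.warns(UserWarning, match="not reliable"):
            ft.holo_stability(apo, binding, 320.0)
        curve = ft.holo_stability_curve(apo, binding,
                                        np.linspace(300.0, 330.0, 7))
        assert curve.reliable is not None
        assert np.array_equal(curve.reliable, curve.temperatures <= 316.2)

    def test_rejects_negative_ligand(self):
        with pytest.raises(ValueError):
            ft.BindingModel(Kb0=1e9, ligand_conc=-1.0)


# -- populations -----------------------------------------------------------

class TestPopulations:
    def test_two_state_midpoint(self):
        t = ft.TransitionThermo(dH_Tm=80.0, dCp=1.0, Tm=330.0)
        prof = ft.populations(ft.MultiStateModel([t]), np.array([330.0]))
        assert prof.fractions[0] == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_three_state_partition_arithmetic(self):
        # K1 = 2, K2 = 3 -> chi = (1/9, 2/9, 6/9)
        T = 298.15
        m = ft.MultiStateModel([
            exact_dg_transition(-R * T * math.log(2), T=T, label="F-to-I"),
            exact_dg_transition(-R * T * math.log(3), T=T, label="I-to-U"),
        ])
        prof = ft.populations(m, np.array([T]))
        assert prof.fractions[0] == pytest.approx(
            [1 / 9, 2 / 9, 6 / 9], abs=1e-12)
        assert prof.state_labels == ("folded", "intermediate", "unfolded")

    def test_two_state_k3(self):
        T = 298.15
        m = ft.MultiStateModel([exact_dg_transition(-R * T * math.log(3), T=T)])
        prof = ft.populations(m, np.array([T]))
        assert prof.fractions[0, 1] == pytest.approx(0.75, abs=1e-12)

    @given(dg1=st.floats(-50.0, 50.0), dg2=st.floats(-50.0, 50.0))
    def test_rows_sum_to_one_at_extreme_stability(self, dg1, dg2):
        T = 298.15
        m = ft.MultiStateModel([
            exact_dg_transition(dg1, T=T, label="F-to-I"),
            exact_dg_transition(dg2, T=T, label="I-to-U"),
        ])
        chi = ft.populations(m, np.array([T])).fractions
        assert abs(chi.sum() - 1.0) < 1e-12
        assert np.all(chi >= 0.0) and np.all(chi <= 1.0)


# -- thermograms -----------------------------------------------------------

def _mean_excess_enthalpy(m, T):
    """Independent oracle: population-weighted cumulative excess
    enthalpy computed from first principles."""
    T = np.atleast_1d(T)
    chi = ft.populations(m, T).fractions
    H = np.zeros_like(chi)
    for k in range(1, chi.shape[1]):
        t = m.transitions[k - 1]
        H[:, k] = H[:, k - 1] + t.dH_Tm + t.dCp * (T - t.Tm)
    return np.sum(chi * H, axis=1)


class TestThermogram:
    def test_two_state_peak_at_tm(self):
        t = ft.TransitionThermo(dH_Tm=110.4, dCp=1.0, Tm=325.0)
        curve = ft.thermogram(ft.MultiStateModel([t]), np.array([325.0]))
        expected_excess = 110.4**2 / (4 * R * 325.0**2)
        assert curve.cp_excess[0] == pytest.approx(expected_excess, rel=1e-9)
        # baseline at the midpoint is chi_U * dCp = dCp / 2
        assert curve.cp_apparent[0] == pytest.approx(
            expected_excess + 0.5, rel=1e-9)

    def test_null_transition_is_flat_zero(self):
        t = ft.TransitionThermo(dH_Tm=0.0, dCp=0.0, Tm=330.0)
        curve = ft.thermogram(ft.MultiStateModel([t]),
                              np.linspace(280.0, 380.0, 11))
        assert np.allclose(curve.cp_apparent, 0.0, atol=1e-12)

    @pytest.mark.parametrize("model", [
        ft.MultiStateModel([ft.TransitionThermo(110.4, 1.0, 325.0)]),
        ft.MultiStateModel([
            ft.TransitionThermo(35.6, 1.5, 316.2, label="F-to-I"),
            ft.TransitionThermo(48.1, 1.0, 329.0, label="I-to-U"),
        ]),
    ], ids=["two-state", "three-state"])
    def test_analytic_equals_numeric_derivative(self, model):
        grid = np.linspace(290.0, 360.0, 141)
        curve = ft.thermogram(model, grid)
        h = 0.01
        numeric = (_mean_excess_enthalpy(model, grid + h)
                   - _mean_excess_enthalpy(model, grid - h)) / (2 * h)
        assert np.max(np.abs(curve.cp_apparent - numeric)) < 1e-4

    def test_two_state_excess_nonnegative(self):
        t = ft.TransitionThermo(dH_Tm=80.0, dCp=1.2, Tm=330.0)
        curve = ft.thermogram(ft.MultiStateModel([t]),
                              np.linspace(280.0, 380.0, 51))
        assert np.all(curve.cp_excess >= 0.0)


class TestStabilityCurve:
    def test_single_transition_zero_at_tm(self, fi_transition):
        curve = ft.stability_curve(ft.MultiStateModel([fi_transition]),
                                   np.array([300.0, 316.2, 330.0]))
        assert abs(curve.dG[1]) < 1e-9

    def test_holo_curve_equals_scalar_calls(self):
        apo = ft.MultiStateModel([exact_dg_transition(4.3)])
        b = ft.BindingModel(Kb0=3.61e9, dH_bind=-11.0, dCp_bind=-0.6)
        grid = np.linspace(280.0, 310.0, 4)
        curve = ft.holo_stability_curve(apo, b, grid)
        for T, dg in zip(grid, curve.dG):
            scalar, _ = ft.holo_stability(apo, b, T, warn_unreliable=False)
            assert dg == pytest.approx(scalar, rel=1e-12)
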