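"""Closed-form folding thermodynamics.

The central object is the Gibbs-Helmholtz equation under a
temperature-independent heat capacity change,

    dG(T) = dH_Tm * (1 - T/Tm) - dCp * [(Tm - T) + T * ln(T/Tm)],

which turns an unfolding enthalpy at the melting temperature and a
dCp into a full stability curve.  On top of it this module provides
delta-method error propagation, dCp extraction as the slope of
dH vs T, sequential-multistate sums, a ligand-concentration
correction for holoproteins (van't Hoff temperature dependence of
the binding constant), Boltzmann state populations and calorimetric
thermograms.

Sign convention: dG_unf > 0 means the folded state is favoured;
K = [U]/[F] = exp(-dG_unf / RT).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats
from scipy.special import softmax

from .models import (
    BindingModel,
    MultiStateModel,
    PopulationProfile,
    StabilityCurve,
    ThermogramCurve,
    TransitionThermo,
)

#: Gas constant in kcal/(mol K).
R = 1.987e-3
#: Standard reference temperature (25 C) in K.
T_REF = 298.15

__all__ = [
    "R",
    "T_REF",
    "gibbs_helmholtz",
    "gh_gradient",
    "propagate_gh_error",
    "DcpFit",
    "fit_dcp",
    "extrapolate_dh",
    "multistate_dG",
    "additive_dcp",
    "vant_hoff_kb",
    "holo_stability",
    "holo_dcp_estimate",
    "stability_curve",
    "holo_stability_curve",
    "populations",
    "thermogram",
    "ddg",
]


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    return T


def gibbs_helmholtz(t: TransitionThermo, T):
    """Unfolding free energy dG_unf(T) in kcal/mol.

    Accepts a scalar temperature or an array; vanishes exactly at
    ``t.Tm``.  Positive values mean the folded state is favoured.
    """
    T = _check_temperature(T)
    dG = (t.dH_Tm * (1.0 - T / t.Tm)
          - t.dCp * ((t.Tm - T) + T * np.log(T / t.Tm)))
    return float(dG) if dG.ndim == 0 else dG


def gh_gradient(t: TransitionThermo, T):
    """Partial derivatives of dG(T) w.r.t. (dH_Tm, dCp, Tm).

    Used by the delta-method error propagation; exposed so tests can
    compare against finite differences.
    """
    T = _check_temperature(T)
    d_dH = 1.0 - T / t.Tm
    d_dCp = -((t.Tm - T) + T * np.log(T / t.Tm))
    d_Tm = t.dH_Tm * T / t.Tm**2 - t.dCp * (1.0 - T / t.Tm)
    return d_dH, d_dCp, d_Tm


def propagate_gh_error(t: TransitionThermo, T):
    """First-order (delta-method) SE of dG(T), assuming independent
    errors in dH_Tm, dCp and Tm.  Returns 0 when all SEs are 0."""
    d_dH, d_dCp, d_Tm = gh_gradient(t, T)
    var = ((d_dH * t.se_dH) ** 2
           + (d_dCp * t.se_dCp) ** 2
           + (d_Tm * t.se_Tm) ** 2)
    se = np.sqrt(var)
    return float(se) if np.ndim(se) == 0 else se


class DcpFit:
    """Result of the linear fit of dH versus T.

    The slope is the heat capacity change dCp (kcal/mol/K); the line
    extrapolates dH to any temperature, in particular to Tm.

    Attributes
    ----------
    slope, intercept : float
        OLS estimates (dH = intercept + slope * T).
    se_slope, se_intercept : float
        Standard errors from the OLS covariance; 0 with
        ``exact_fit=True`` when only two points were supplied
        (no residual degrees of freedom).
    """

    def __init__(self, slope, intercept, se_slope, se_intercept,
                 n, exact_fit=False, xbar=None):
        self.slope = float(slope)
        self.intercept = float(intercept)
        self.se_slope = float(se_slope)
        self.se_intercept = float(se_intercept)
        self.n = int(n)
        self.exact_fit = bool(exact_fit)
        self.xbar = None if xbar is None else float(xbar)

    def predict(self, T):
        return self.intercept + self.slope * np.asarray(T, dtype=float)

    def __repr__(self):
        return (f"DcpFit(slope={self.slope:.4g}, intercept={self.intercept:.4g}, "
                f"se_slope={self.se_slope:.3g}, n={self.n})")


def fit_dcp(points, se=None) -> DcpFit:
    """Fit dCp as the slope of a dH vs T ordinary least-squares line.

    Parameters
    ----------
    points : sequence of (T, dH)
        At least two points with distinct temperatures.
    se : sequence of float, optional
        Known per-point SEs of dH (e.g. the combined replica SEs).
        When given, the point estimates are still plain OLS but the
        slope/intercept SEs are obtained by propagating these known
        errors through the OLS estimator instead of from the
        residuals — with only three temperatures the residual
        variance has a single degree of freedom, whereas the replica
        SEs are well determined.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least two (T, dH) points")
    T, dH = pts[:, 0], pts[:, 1]
    if np.unique(T).size < 2:
        raise ValueError("temperatures must not all be equal")
    res = stats.linregress(T, dH)
    n = T.size
    if se is not None:
        se = np.asarray(list(se), dtype=float)
        if se.shape != T.shape or np.any(se < 0):
            raise ValueError("se must give one non-negative value per point")
        # y_i enters slope with weight c_i = (T_i - Tbar)/Sxx and the
        # intercept with weight 1/n - Tbar*c_i
        sxx = np.sum((T - T.mean()) ** 2)
        c = (T - T.mean()) / sxx
        se_slope = math.sqrt(np.sum((c * se) ** 2))
        se_intercept = math.sqrt(np.sum(((1.0 / n - T.mean() * c) * se) ** 2))
        return DcpFit(res.slope, res.intercept, se_slope, se_intercept,
                      n, xbar=float(T.mean()))
    if n == 2:
        # exact line: SEs undefined, flagged instead of NaN
        return DcpFit(res.slope, res.intercept, 0.0, 0.0, n,
                      exact_fit=True, xbar=float(T.mean()))
    return DcpFit(res.slope, res.intercept, res.stderr,
                  res.intercept_stderr, n, xbar=float(T.mean()))


def extrapolate_dh(fit: DcpFit, Tm: float):
    """dH extrapolated to ``Tm`` along the fitted line, with its SE.

    The SE accounts for the full OLS covariance of slope and
    intercept, i.e. se^2 = se_b^2 + Tm^2 se_m^2 + 2 Tm cov(b, m);
    with centred predictors this is the standard prediction-SE of the
    mean response.  Returns ``(dH_at_Tm, se)``.
    """
    value = float(fit.predict(Tm))
    if fit.exact_fit:
        return value, 0.0
    # OLS identities: var(slope) = s2/Sxx, se_intercept^2 = var_m*mean(x^2),
    # cov(intercept, slope) = -xbar*var_m, hence
    # var(pred at x0) = var_m * (x0^2 - 2*x0*xbar + mean(x^2)).
    var_m = fit.se_slope**2
    if var_m == 0 or fit.xbar is None:
        return value, math.sqrt(fit.se_intercept**2 + (Tm * fit.se_slope) ** 2)
    mean_x2 = fit.se_intercept**2 / var_m
    se = math.sqrt(max(var_m * (Tm**2 - 2 * Tm * fit.xbar + mean_x2), 0.0))
    return value, se


def multistate_dG(m: MultiStateModel, T, se_mode: str = "quadrature"):
    """Per-transition dG values at ``T`` plus their global sum.

    The global stability of a sequential pathway is the sum of the
    individual free-energy changes.  ``se_mode`` chooses how the
    per-transition SEs combine into the global SE: ``"quadrature"``
    (independent transitions, default) or ``"sum"``.

    Returns ``(per_transition, (global_dG, global_se))`` where
    ``per_transition`` is a list of ``(dG, se)`` pairs ordered like
    ``m.transitions``.
    """
    if se_mode not in ("sum", "quadrature"):
        raise ValueError(f"se_mode must be 'sum' or 'quadrature', got {se_mode!r}")
    per = [(gibbs_helmholtz(t, T), propagate_gh_error(t, T))
           for t in m.transitions]
    total = sum(v for v, _ in per)
    if se_mode == "sum":
        se = sum(s for _, s in per)
    else:
        se = np.sqrt(sum(np.square(s) for _, s in per))
    if np.ndim(total) == 0:
        return per, (float(total), float(se))
    return per, (total, se)


def additive_dcp(m: MultiStateModel, se_mode: str = "quadrature"):
    """Global dCp as the sum of per-transition dCp values.

    Returns ``(dCp_global, se)`` with SEs combined per ``se_mode``.
    """
    if se_mode not in ("sum", "quadrature"):
        raise ValueError(f"se_mode must be 'sum' or 'quadrature', got {se_mode!r}")
    total = sum(t.dCp for t in m.transitions)
    if se_mode == "sum":
        se = sum(t.se_dCp for t in m.transitions)
    else:
        se = math.sqrt(sum(t.se_dCp**2 for t in m.transitions))
    return total, se


def vant_hoff_kb(b: BindingModel, T, constant_dh: bool = False):
    """Binding constant Kb(T) by the integrated van't Hoff relation.

    The binding enthalpy is taken linear in temperature,
    dH_bind(T) = dH_bind(T0) + dCp_bind * (T - T0); integrating
    d ln K / dT = dH / (R T^2) gives

        ln K(T) = ln K0
                  - (dH0 - dCp*T0)/R * (1/T - 1/T0)
                  + dCp/R * ln(T/T0).

    ``constant_dh=True`` drops the dCp_bind term (classic constant-
    enthalpy van't Hoff).  All variants coincide at T = T0.
    """
    T = _check_temperature(T)
    dcp = 0.0 if constant_dh else b.dCp_bind
    lnk = (math.log(b.Kb0)
           - (b.dH_bind - dcp * b.T0) / R * (1.0 / T - 1.0 / b.T0)
           + dcp / R * np.log(T / b.T0))
    K = np.exp(lnk)
    return float(K) if np.ndim(K) == 0 else K


def holo_stability(apo: MultiStateModel, b: BindingModel, T,
                   se_mode: str = "quadrature",
                   saturating_approx: bool = False,
                   warn_unreliable: bool = True):
    """Holoprotein stability: apo stability plus the ligand correction.

    dG_holo(T) = dG_apo_global(T) + R*T*ln(1 + Kb(T) * [L]).

    With ``saturating_approx=True`` the correction is R*T*ln(Kb*[L]),
    valid when Kb*[L] >> 1.  At [L] = 0 the correction vanishes and
    the apo stability is returned.

    The van't Hoff description of Kb(T) assumes an intact binding
    site, so values above the first apo melting temperature are not
    reliable; a ``UserWarning`` is emitted there (see
    :func:`holo_stability_curve` for an explicit mask).

    Returns ``(dG_holo, se)``; the SE is the propagated apo SE (the
    binding parameters enter without uncertainty here).
    """
    T = _check_temperature(T)
    _, (dg_apo, se_apo) = multistate_dG(apo, T, se_mode=se_mode)
    kb = vant_hoff_kb(b, T)
    if saturating_approx:
        if b.ligand_conc <= 0:
            raise ValueError("saturating approximation needs [L] > 0")
        corr = R * T * (np.log(kb) + math.log(b.ligand_conc))
    else:
        corr = R * T * np.log1p(kb * b.ligand_conc)
    if warn_unreliable and np.any(T > apo.first_Tm):
        warnings.warn(
            "holo stability above the first apo Tm "
            f"({apo.first_Tm:.1f} K) is not reliable", stacklevel=2)
    dg = dg_apo + corr
    if np.ndim(dg) == 0:
        return float(dg), float(se_apo)
    return dg, se_apo


def holo_dcp_estimate(dcp_apo, dcp_bind, se_dcp_apo=0.0, se_dcp_bind=0.0):
    """Holoprotein dCp_unf estimated from the apo value plus cofactor
    dissociation: dCp_holo = dCp_apo + (-dCp_bind).

    Returns ``(dCp_holo, se)`` with SEs combined in quadrature.
    """
    return (dcp_apo - dcp_bind,
            math.sqrt(se_dcp_apo**2 + se_dcp_bind**2))


def stability_curve(m: MultiStateModel, T_grid,
                    se_mode: str = "quadrature") -> StabilityCurve:
    """Global stability curve dG_unf(T) over a temperature grid."""
    T = _check_temperature(T_grid)
    dg = np.zeros_like(T)
    ses = []
    for t in m.transitions:
        dg += gibbs_helmholtz(t, T)
        ses.append(propagate_gh_error(t, T))
    if se_mode == "sum":
        se = np.sum(ses, axis=0)
    else:
        se = np.sqrt(np.sum(np.square(ses), axis=0))
    return StabilityCurve(T, dg, se_dG=se)


def holo_stability_curve(apo: MultiStateModel, b: BindingModel, T_grid,
                         se_mode: str = "quadrature") -> StabilityCurve:
    """Holo stability curve with an explicit reliability mask
    (False above the first apo melting temperature)."""
    T = _check_temperature(T_grid)
    dg, se = holo_stability(apo, b, T, se_mode=se_mode,
                            warn_unreliable=False)
    reliable = T <= apo.first_Tm
    return StabilityCurve(T, np.atleast_1d(dg),
                          se_dG=np.atleast_1d(se) * np.ones_like(T),
                          reliable=reliable)


def _cumulative_dG(m: MultiStateModel, T):
    """Cumulative dG of states 0..n over grid T; shape (n_T, n_states)."""
    T = np.atleast_1d(np.asarray(T, dtype=float))
    per = np.stack([gibbs_helmholtz(t, T) * np.ones_like(T)
                    for t in m.transitions], axis=1)
    cum = np.cumsum(per, axis=1)
    return np.concatenate([np.zeros((T.size, 1)), cum], axis=1)


def _cumulative_dH(m: MultiStateModel, T):
    """Cumulative excess enthalpy H_k(T) relative to folded,
    H_k = sum_{j<=k} [dH_Tm_j + dCp_j (T - Tm_j)]; shape (n_T, n_states)."""
    T = np.atleast_1d(np.asarray(T, dtype=float))
    per = np.stack([(t.dH_Tm + t.dCp * (T - t.Tm)) for t in m.transitions],
                   axis=1)
    cum = np.cumsum(per, axis=1)
    return np.concatenate([np.zeros((T.size, 1)), cum], axis=1)


def populations(m: MultiStateModel, T_grid) -> PopulationProfile:
    """Equilibrium molar fractions of the folding states.

    With K1 = exp(-dG_FI/RT) and K2 = exp(-dG_IU/RT) the three-state
    partition function is Q = 1 + K1 + K1*K2 and
    chi_F = 1/Q, chi_I = K1/Q, chi_U = K1*K2/Q (two-state:
    Q = 1 + K).  Evaluation is in log space (softmax over -G_cum/RT)
    so extreme stabilities do not overflow.
    """
    T = _check_temperature(np.atleast_1d(T_grid))
    g_cum = _cumulative_dG(m, T)
    log_w = -g_cum / (R * T[:, None])
    chi = softmax(log_w, axis=1)
    return PopulationProfile(T, chi, tuple(m.state_labels()))


def thermogram(m: MultiStateModel, T_grid) -> ThermogramCurve:
    """Calorimetric thermogram: excess Cp plus population-weighted
    baseline, as a DSC instrument would report it.

    The excess term is evaluated analytically as the Boltzmann
    variance of the cumulative excess enthalpy,

        Cp_excess(T) = [<H^2> - <H>^2] / (R T^2),

    which for a two-state system reduces to
    chi_F * chi_U * dH(T)^2 / (R T^2).  The baseline is
    sum_k chi_k * dCp_cum,k with the folded-state Cp as the zero
    reference.  The sum equals the total derivative d<H>/dT of the
    population-weighted excess enthalpy.
    """
    T = _check_temperature(np.atleast_1d(T_grid))
    chi = populations(m, T).fractions
    H = _cumulative_dH(m, T)
    mean_H = np.sum(chi * H, axis=1)
    var_H = np.sum(chi * H**2, axis=1) - mean_H**2
    excess = var_H / (R * T**2)
    dcp_cum = np.concatenate(
        [[0.0], np.cumsum([t.dCp for t in m.transitions])])
    baseline = chi @ dcp_cum
    return ThermogramCurve(T, excess + baseline,
                           cp_excess=excess, baseline=baseline)


def ddg(dG_b, dG_a, se_b=0.0, se_a=0.0):
    """Stability difference ddG = dG_b - dG_a (b relative to a),
    with SEs combined in quadrature.  Returns ``(ddG, se)``."""
    return dG_b - dG_a, math.sqrt(se_b**2 + se_a**2)
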