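"""Replica-level enthalpy statistics.

Each MD replica contributes one time-averaged enthalpy; replicas of
the same folding state at the same temperature are ensemble-averaged,
and the unfolding enthalpy change is the difference of the ensemble
means (unfolded minus folded, or I minus F / U minus I for a
three-state pathway).  Repeating this at three temperatures yields
the dH(T) points whose slope is dCp (see :func:`foldtherm.thermo.fit_dcp`).

Absolute box enthalpies are large (order -1e5 kcal/mol, dominated by
solvent), so differences demand low standard errors; the sample-size
planner converts a pilot SD into the replica count needed for a
target SE.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np
from scipy import stats

from .models import (
    EnsembleEnthalpy,
    EnthalpyDifference,
    ReplicaEnergySeries,
    SampleSizePlan,
)

KJ_PER_KCAL = 4.184

__all__ = [
    "KJ_PER_KCAL",
    "time_average",
    "ensemble_average",
    "enthalpy_difference",
    "transition_series",
    "min_sample_size",
    "plan_sample_size",
    "rg_drift_check",
]


def time_average(series: ReplicaEnergySeries,
                 equilibration_cut: float = 0.0) -> float:
    """Time-averaged enthalpy of one replica.

    Frames with ``time <= equilibration_cut`` are discarded; the
    default cut of 0 keeps everything (productive trajectories are
    assumed already equilibrated).
    """
    mask = series.times > equilibration_cut
    if not np.any(mask):
        raise ValueError(
            f"no samples after equilibration cut {equilibration_cut}")
    return float(series.enthalpies[mask].mean())


def ensemble_average(values, state_label: str,
                     temperature: float) -> EnsembleEnthalpy:
    """Ensemble average over replica means for one state/temperature.

    SD uses the n-1 denominator; SE = SD/sqrt(n).  A single replica
    yields SD = SE = 0 (no spread information).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("ensemble_average needs at least one replica mean")
    if v.size == 1:
        sd = 0.0
    else:
        sd = float(v.std(ddof=1))
    se = sd / math.sqrt(v.size)
    return EnsembleEnthalpy(state_label=state_label, temperature=temperature,
                            mean_H=float(v.mean()), sd=sd, se=se, n=v.size)


def enthalpy_difference(upper: EnsembleEnthalpy, lower: EnsembleEnthalpy,
                        se_mode: str = "sum") -> EnthalpyDifference:
    """dH = upper.mean_H - lower.mean_H at a common temperature.

    The default SE combination is the simple sum of the two ensemble
    SEs (the reporting convention for replica-difference enthalpies);
    ``se_mode="quadrature"`` gives the independent-errors combination,
    which is never larger.
    """
    if upper.temperature != lower.temperature:
        raise ValueError(
            f"temperature mismatch: {upper.temperature} vs {lower.temperature}")
    if se_mode == "sum":
        se = upper.se + lower.se
    elif se_mode == "quadrature":
        se = math.hypot(upper.se, lower.se)
    else:
        raise ValueError(f"se_mode must be 'sum' or 'quadrature', got {se_mode!r}")
    return EnthalpyDifference(
        dH=upper.mean_H - lower.mean_H, se_dH=se,
        temperature=upper.temperature,
        from_state=lower.state_label, to_state=upper.state_label)


def transition_series(ensembles, from_state: str, to_state: str,
                      se_mode: str = "sum"):
    """Collect (T, dH) points for one transition across temperatures.

    Parameters
    ----------
    ensembles : iterable of EnsembleEnthalpy
        State averages at several temperatures; every temperature must
        provide both ``from_state`` and ``to_state``.

    Returns
    -------
    points, ses : list of (T, dH), list of SE
        Sorted by temperature, ready for :func:`foldtherm.thermo.fit_dcp`.
    """
    by_T: dict[float, dict[str, EnsembleEnthalpy]] = defaultdict(dict)
    for e in ensembles:
        if e.state_label in (from_state, to_state):
            if e.state_label in by_T[e.temperature]:
                raise ValueError(
                    f"duplicate ensemble for {e.state_label} at {e.temperature} K")
            by_T[e.temperature][e.state_label] = e
    points, ses = [], []
    for T in sorted(by_T):
        pair = by_T[T]
        if set(pair) != {from_state, to_state}:
            raise ValueError(
                f"temperature {T} K is missing one of "
                f"({from_state!r}, {to_state!r})")
        d = enthalpy_difference(pair[to_state], pair[from_state],
                                se_mode=se_mode)
        points.append((T, d.dH))
        ses.append(d.se_dH)
    if not points:
        raise ValueError("no matching state pairs found")
    return points, ses


def min_sample_size(pilot_sd: float, target_se: float) -> int:
    """Smallest replica count n with pilot_sd/sqrt(n) <= target_se,
    i.e. ceil((pilot_sd/target_se)^2), floored at 1."""
    if target_se <= 0:
        raise ValueError("target_se must be positive")
    if pilot_sd < 0:
        raise ValueError("pilot_sd must be non-negative")
    if pilot_sd <= target_se:
        return 1
    ratio = (pilot_sd / target_se) ** 2
    # guard against float fuzz at exact squares (e.g. 50/10 -> 25)
    n = math.ceil(ratio - 1e-9)
    return max(n, 1)


def plan_sample_size(state_label: str, pilot_sd: float,
                     target_se: float) -> SampleSizePlan:
    return SampleSizePlan(state_label=state_label, pilot_sd=pilot_sd,
                          target_se=target_se,
                          n_required=min_sample_size(pilot_sd, target_se))


def rg_drift_check(rg_series, rel_tol: float = 0.05):
    """Overcompaction check on a radius-of-gyration trajectory.

    Fits Rg vs time by OLS and converts the slope into a relative
    change over the observation window (slope * span / mean Rg).
    Fails when the relative *decrease* exceeds ``rel_tol`` (default
    5%), i.e. the chain is collapsing.

    Returns ``(passed, relative_change)``; positive change = expansion.
    """
    arr = np.asarray(list(rg_series), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("need at least two (time, Rg) samples")
    t, rg = arr[:, 0], arr[:, 1]
    mean_rg = rg.mean()
    if mean_rg <= 0:
        raise ValueError("mean Rg must be positive")
    if np.unique(t).size < 2:
        raise ValueError("times must span a window")
    slope = stats.linregress(t, rg).slope
    rel_change = slope * (t.max() - t.min()) / mean_rg
    return rel_change >= -rel_tol, float(rel_change)
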