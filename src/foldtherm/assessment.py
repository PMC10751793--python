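"""Calculated-versus-experimental assessment.

A method that computes folding energetics from simulation is judged
by regressing its calculated dH, dCp and dG values (y) on the
experimentally determined ones (x): an accurate method gives a slope
near 1, an intercept near 0 and a high R^2.

The package bundles a benchmark table of published calculated and
experimental unfolding energetics for barnase, staphylococcal
nuclease (three pH conditions), CI2 (wild type at two pH values plus
the Ile76Ala cavity mutant), the three-state apoflavodoxin pathway
(F-to-I, I-to-U and global F-to-U) and FMN-bound holoflavodoxin,
with T4 lysozyme entries and low-pH nuclease flagged as outliers;
cells not available in the source compilation are left empty.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .models import FitReport, PairedObservation

__all__ = [
    "calc_vs_exp_fit",
    "load_benchmark_table",
    "benchmark_fit",
    "pairs_to_frame",
]

_DATA_PACKAGE = "foldtherm.data"
_BENCHMARK_CSV = "benchmark_folding_energetics.csv"


def load_benchmark_table() -> list[PairedObservation]:
    """Load the bundled benchmark of calculated-vs-experimental
    unfolding energetics as :class:`PairedObservation` records.

    Outlier flags mark systems excluded from the assessment fits by
    inspection (the four T4 lysozyme systems and nuclease at pH 4.1);
    missing cells are NaN.
    """
    with resources.files(_DATA_PACKAGE).joinpath(_BENCHMARK_CSV).open() as fh:
        df = pd.read_csv(fh)
    obs = []
    for row in df.itertuples(index=False):
        obs.append(PairedObservation(
            system_id=row.system_id,
            quantity=row.quantity,
            experimental=float(row.exp) if pd.notna(row.exp) else math.nan,
            calculated=float(row.calc) if pd.notna(row.calc) else math.nan,
            exp_se=float(row.exp_se) if pd.notna(row.exp_se) else math.nan,
            calc_se=float(row.calc_se) if pd.notna(row.calc_se) else math.nan,
            units=row.units,
            outlier=bool(row.outlier),
        ))
    return obs


def pairs_to_frame(pairs) -> pd.DataFrame:
    """Tabulate observations as a DataFrame (one row per pair)."""
    return pd.DataFrame([{
        "system_id": p.system_id, "quantity": p.quantity,
        "exp": p.experimental, "exp_se": p.exp_se,
        "calc": p.calculated, "calc_se": p.calc_se,
        "units": p.units, "outlier": p.outlier,
    } for p in pairs])


def calc_vs_exp_fit(pairs, exclude=(), include_outliers: bool = False) -> FitReport:
    """OLS fit of calculated (y) on experimental (x) values.

    Pairs flagged as outliers, listed in ``exclude`` (by system_id)
    or missing either value are dropped before fitting; R^2 is the
    squared Pearson correlation.
    """
    exclude = set(exclude)
    used, dropped = [], []
    for p in pairs:
        if p.system_id in exclude or (p.outlier and not include_outliers):
            dropped.append(p.system_id)
            continue
        if not (math.isfinite(p.experimental) and math.isfinite(p.calculated)):
            dropped.append(p.system_id)
            continue
        used.append(p)
    if len(used) < 2:
        raise ValueError(f"need at least 2 usable pairs, got {len(used)}")
    x = np.array([p.experimental for p in used])
    y = np.array([p.calculated for p in used])
    res = stats.linregress(x, y)
    return FitReport(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=min(float(res.rvalue) ** 2, 1.0), n_used=len(used),
        excluded=tuple(dict.fromkeys(dropped)),
        se_slope=float(res.stderr), se_intercept=float(res.intercept_stderr))


def benchmark_fit(quantity: str, **kwargs) -> FitReport:
    """Assessment fit for one quantity ('dH' | 'dCp' | 'dG') over the
    bundled benchmark table."""
    pairs = [p for p in load_benchmark_table() if p.quantity == quantity]
    if not pairs:
        raise ValueError(f"unknown quantity {quantity!r}")
    return calc_vs_exp_fit(pairs, **kwargs)
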