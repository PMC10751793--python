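"""File formats: XVG-style energy series, parameter tables, curves.

XVG files are the whitespace-delimited two-column (time, energy)
series emitted by common MD analysis tools; lines starting with '#'
(comments) or '@' (plot directives) are ignored.  Transition and
binding parameter tables round-trip through CSV, JSON and YAML;
computed curves are written as plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import (
    BindingModel,
    MultiStateModel,
    PopulationProfile,
    ReplicaEnergySeries,
    StabilityCurve,
    ThermogramCurve,
    TransitionThermo,
)
from .replicas import KJ_PER_KCAL

__all__ = [
    "read_xvg",
    "write_xvg",
    "read_transitions",
    "write_transitions",
    "read_binding",
    "write_curve",
    "write_populations",
    "write_replica_summary",
    "read_replica_summary",
]

TRANSITION_COLUMNS = ["label", "dH_Tm", "se_dH", "dCp", "se_dCp", "Tm", "se_Tm"]


def read_xvg(path, replica_id=None, state_label="folded",
             temperature=298.15, units="kcal") -> ReplicaEnergySeries:
    """Read an XVG-style (time, energy) series.

    ``units="kJ"`` converts the energy column to kcal/mol (divide by
    4.184); the internal unit is always kcal/mol.
    """
    if units not in ("kcal", "kJ"):
        raise ValueError(f"units must be 'kcal' or 'kJ', got {units!r}")
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "@")):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"malformed XVG line: {line!r}")
        rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError(f"no data rows in {path}")
    arr = np.asarray(rows)
    energy = arr[:, 1] / KJ_PER_KCAL if units == "kJ" else arr[:, 1]
    return ReplicaEnergySeries(
        replica_id=replica_id or Path(path).stem,
        state_label=state_label, temperature=temperature,
        times=arr[:, 0], enthalpies=energy)


def write_xvg(series: ReplicaEnergySeries, path, comment: str = "") -> None:
    lines = [f"# {comment}" if comment else "# enthalpy time series (kcal/mol)",
             f"# replica {series.replica_id} state {series.state_label} "
             f"T {series.temperature} K"]
    lines += [f"{t:.6f} {h:.6f}"
              for t, h in zip(series.times, series.enthalpies)]
    Path(path).write_text("\n".join(lines) + "\n")


def _transition_from_record(rec: dict) -> TransitionThermo:
    return TransitionThermo(
        label=str(rec["label"]),
        dH_Tm=float(rec["dH_Tm"]), se_dH=float(rec.get("se_dH", 0) or 0),
        dCp=float(rec["dCp"]), se_dCp=float(rec.get("se_dCp", 0) or 0),
        Tm=float(rec["Tm"]), se_Tm=float(rec.get("se_Tm", 0) or 0))


def read_transitions(path) -> MultiStateModel:
    """Read an ordered transition table (CSV, JSON or YAML by
    extension) into a :class:`MultiStateModel`."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        records = pd.read_csv(path).to_dict("records")
    elif suffix == ".json":
        records = json.loads(path.read_text())
    elif suffix in (".yaml", ".yml"):
        records = yaml.safe_load(path.read_text())
    else:
        raise ValueError(f"unsupported transition table format: {suffix}")
    if isinstance(records, dict):
        records = records["transitions"]
    return MultiStateModel([_transition_from_record(r) for r in records])


def write_transitions(m: MultiStateModel, path) -> None:
    path = Path(path)
    rows = [{"label": t.label, "dH_Tm": t.dH_Tm, "se_dH": t.se_dH,
             "dCp": t.dCp, "se_dCp": t.se_dCp, "Tm": t.Tm, "se_Tm": t.se_Tm}
            for t in m.transitions]
    suffix = path.suffix.lower()
    if suffix == ".csv":
        pd.DataFrame(rows, columns=TRANSITION_COLUMNS).to_csv(path, index=False)
    elif suffix == ".json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
    elif suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(rows, sort_keys=False))
    else:
        raise ValueError(f"unsupported transition table format: {suffix}")


def read_binding(path) -> BindingModel:
    """Read binding parameters (JSON or YAML mapping with keys Kb0,
    T0, dH_bind, dCp_bind, ligand_conc)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rec = json.loads(path.read_text())
    else:
        rec = yaml.safe_load(path.read_text())
    return BindingModel(**{k: float(v) for k, v in rec.items()})


def write_curve(curve, path, value_name: str = "value") -> None:
    """Write a stability or thermogram curve as CSV (T, value[, se])."""
    if isinstance(curve, StabilityCurve):
        df = pd.DataFrame({"T_K": curve.temperatures,
                           value_name: curve.dG})
        if curve.se_dG is not None:
            df["se"] = curve.se_dG
        if curve.reliable is not None:
            df["reliable"] = curve.reliable
    elif isinstance(curve, ThermogramCurve):
        df = pd.DataFrame({"T_K": curve.temperatures,
                           value_name: curve.cp_apparent})
        if curve.cp_excess is not None:
            df["cp_excess"] = curve.cp_excess
            df["baseline"] = curve.baseline
    else:
        raise TypeError(f"cannot serialise {type(curve).__name__}")
    df.to_csv(path, index=False)


def write_populations(profile: PopulationProfile, path) -> None:
    df = pd.DataFrame(profile.fractions, columns=list(profile.state_labels))
    df.insert(0, "T_K", profile.temperatures)
    df.to_csv(path, index=False)


def write_replica_summary(rows, path) -> None:
    """Write replica means as CSV (replica_id, state, T, mean_H)."""
    pd.DataFrame(rows, columns=["replica_id", "state", "T", "mean_H"]).to_csv(
        path, index=False)


def read_replica_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"replica_id", "state", "T", "mean_H"} - set(df.columns)
    if missing:
        raise ValueError(f"replica summary missing columns: {sorted(missing)}")
    return df
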