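"""Domain containers for folding-thermodynamics calculations.

Units follow calorimetric convention throughout: energies in kcal/mol,
heat capacities in kcal/(mol K), temperatures in K, coordinates in
angstroms (boxes reported in nm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransitionThermo",
    "MultiStateModel",
    "BindingModel",
    "StabilityCurve",
    "PopulationProfile",
    "ThermogramCurve",
    "ReplicaEnergySeries",
    "EnsembleEnthalpy",
    "EnthalpyDifference",
    "SampleSizePlan",
    "Conformation",
    "ConformationEnsemble",
    "BoxSpec",
    "SystemComposition",
    "PairedObservation",
    "FitReport",
]


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name}: non-finite value {v!r}")


@dataclass(frozen=True)
class TransitionThermo:
    """One unfolding transition: enthalpy change at the midpoint, heat
    capacity change and melting temperature, with standard errors.

    Parameters
    ----------
    dH_Tm : float
        Unfolding enthalpy change evaluated at ``Tm`` (kcal/mol).
    dCp : float
        Heat capacity change upon unfolding (kcal/mol/K), assumed
        temperature independent.
    Tm : float
        Melting temperature (K), where the two states are equally
        populated (dG = 0).
    se_dH, se_dCp, se_Tm : float, optional
        Standard errors of the three parameters (default 0).
    label : str
        Free-text state pair, e.g. ``"F-to-U"`` or ``"F-to-I"``.
    """

    dH_Tm: float
    dCp: float
    Tm: float
    se_dH: float = 0.0
    se_dCp: float = 0.0
    se_Tm: float = 0.0
    label: str = "F-to-U"

    def __post_init__(self) -> None:
        _check_finite(
            "TransitionThermo",
            self.dH_Tm, self.dCp, self.Tm, self.se_dH, self.se_dCp, self.se_Tm,
        )
        if self.Tm <= 0:
            raise ValueError(f"Tm must be positive, got {self.Tm}")
        if min(self.se_dH, self.se_dCp, self.se_Tm) < 0:
            raise ValueError("standard errors must be non-negative")


@dataclass(frozen=True)
class MultiStateModel:
    """Ordered sequence of sequential unfolding transitions.

    Two-state proteins carry a single transition (F-to-U); three-state
    proteins carry F-to-I followed by I-to-U.  Global quantities are
    sums over transitions.
    """

    transitions: tuple[TransitionThermo, ...]

    def __init__(self, transitions) -> None:
        transitions = tuple(transitions)
        if not transitions:
            raise ValueError("MultiStateModel needs at least one transition")
        labels = [t.label for t in transitions]
        if len(set(labels)) != len(labels):
            raise ValueError(f"transition labels must be unique, got {labels}")
        object.__setattr__(self, "transitions", transitions)

    @property
    def n_states(self) -> int:
        return len(self.transitions) + 1

    @property
    def first_Tm(self) -> float:
        """Lowest melting temperature along the pathway."""
        return min(t.Tm for t in self.transitions)

    def state_labels(self) -> list[str]:
        if self.n_states == 2:
            return ["folded", "unfolded"]
        if self.n_states == 3:
            return ["folded", "intermediate", "unfolded"]
        return ["folded"] + [f"state_{i}" for i in range(1, self.n_states - 1)] + ["unfolded"]


@dataclass(frozen=True)
class BindingModel:
    """Cofactor-binding energetics for a holoprotein.

    ``Kb0`` is the association constant (1/M) at the reference
    temperature ``T0``; the van't Hoff relation extends it in
    temperature using ``dH_bind`` and ``dCp_bind``.  ``ligand_conc``
    is the free-ligand concentration (M); 1 M gives the standard-state
    stability.
    """

    Kb0: float
    T0: float = 298.15
    dH_bind: float = 0.0
    dCp_bind: float = 0.0
    ligand_conc: float = 1.0
    se_Kb0: float = 0.0
    se_dH_bind: float = 0.0
    se_dCp_bind: float = 0.0

    def __post_init__(self) -> None:
        _check_finite("BindingModel", self.Kb0, self.T0, self.dH_bind,
                      self.dCp_bind, self.ligand_conc)
        if self.Kb0 <= 0:
            raise ValueError(f"Kb0 must be positive, got {self.Kb0}")
        if self.T0 <= 0:
            raise ValueError(f"T0 must be positive, got {self.T0}")
        if self.ligand_conc < 0:
            raise ValueError(f"ligand_conc must be >= 0, got {self.ligand_conc}")


@dataclass(frozen=True)
class StabilityCurve:
    """dG_unf as a function of temperature, optionally with an SE band
    and a per-point reliability mask (holo curves above the first apo
    melting temperature are flagged unreliable)."""

    temperatures: np.ndarray
    dG: np.ndarray
    se_dG: np.ndarray | None = None
    reliable: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        g = np.asarray(self.dG, dtype=float)
        if t.shape != g.shape:
            raise ValueError("temperature and dG grids differ in length")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "dG", g)
        if self.se_dG is not None:
            se = np.asarray(self.se_dG, dtype=float)
            if se.shape != t.shape:
                raise ValueError("se_dG grid differs in length")
            object.__setattr__(self, "se_dG", se)


@dataclass(frozen=True)
class PopulationProfile:
    """Per-state molar fractions chi_i over a temperature grid."""

    temperatures: np.ndarray
    fractions: np.ndarray  # shape (n_T, n_states)
    state_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if f.ndim != 2 or f.shape[0] != t.size:
            raise ValueError("fractions must be (n_T, n_states)")
        if f.shape[1] != len(self.state_labels):
            raise ValueError("one label per state required")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "state_labels", tuple(self.state_labels))


@dataclass(frozen=True)
class ThermogramCurve:
    """Apparent excess heat capacity versus temperature.

    ``cp_apparent`` is the calorimetric observable: the excess Cp of
    the transitions plus the population-weighted baseline
    sum(chi_i * dCp_i).  ``cp_excess`` and ``baseline`` expose the
    two components separately.
    """

    temperatures: np.ndarray
    cp_apparent: np.ndarray
    cp_excess: np.ndarray | None = None
    baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        c = np.asarray(self.cp_apparent, dtype=float)
        if t.shape != c.shape:
            raise ValueError("grids differ in length")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "cp_apparent", c)


STATE_LABELS = ("folded", "intermediate", "unfolded", "holo_folded",
                "unfolded_plus_cofactor")


@dataclass(frozen=True)
class ReplicaEnergySeries:
    """Per-frame enthalpy time series of one simulation replica."""

    replica_id: str
    state_label: str
    temperature: float
    times: np.ndarray
    enthalpies: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.enthalpies, dtype=float)
        if t.size == 0:
            raise ValueError("series needs at least one sample")
        if t.shape != h.shape:
            raise ValueError("times and enthalpies differ in length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.state_label not in STATE_LABELS:
            raise ValueError(
                f"unknown state {self.state_label!r}; expected one of {STATE_LABELS}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "enthalpies", h)


@dataclass(frozen=True)
class EnsembleEnthalpy:
    """Ensemble-averaged enthalpy of one folding state at one
    temperature: mean over replica time averages, with sample SD
    (n-1 denominator) and SE = SD/sqrt(n)."""

    state_label: str
    temperature: float
    mean_H: float
    sd: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if abs(self.se - self.sd / math.sqrt(self.n)) > 1e-12 * max(1.0, self.sd):
            raise ValueError("se must equal sd/sqrt(n)")


@dataclass(frozen=True)
class EnthalpyDifference:
    """dH between two state ensembles at one temperature."""

    dH: float
    se_dH: float
    temperature: float
    from_state: str
    to_state: str

    def __post_init__(self) -> None:
        if self.se_dH < 0:
            raise ValueError("se_dH must be >= 0")


@dataclass(frozen=True)
class SampleSizePlan:
    """Replicas required for a target SE given a pilot SD."""

    state_label: str
    pilot_sd: float
    target_se: float
    n_required: int

    def __post_init__(self) -> None:
        if self.n_required < 1:
            raise ValueError("n_required must be >= 1")


@dataclass(frozen=True)
class Conformation:
    """One member of a structural ensemble: coordinates in angstrom,
    optional per-atom masses (unit masses assumed when absent)."""

    model_id: int
    coords: np.ndarray  # (n_atoms, 3), angstrom
    masses: np.ndarray | None = None
    atom_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 1:
            raise ValueError("coords must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(c)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", c)
        if self.masses is not None:
            m = np.asarray(self.masses, dtype=float)
            if m.shape != (c.shape[0],):
                raise ValueError("one mass per atom required")
            object.__setattr__(self, "masses", m)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class ConformationEnsemble:
    """Multi-model coordinate set with lazily cached per-model
    diameter and radius of gyration."""

    models: list[Conformation]
    _diameters: np.ndarray | None = field(default=None, repr=False)
    _rgs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble must contain at least one model")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def diameters(self) -> np.ndarray:
        from .geometry import molecular_diameter
        if self._diameters is None:
            self._diameters = np.array(
                [molecular_diameter(c) for c in self.models])
        return self._diameters

    def radii_of_gyration(self) -> np.ndarray:
        from .geometry import radius_of_gyration
        if self._rgs is None:
            self._rgs = np.array(
                [radius_of_gyration(c) for c in self.models])
        return self._rgs


@dataclass(frozen=True)
class BoxSpec:
    """Cubic simulation-box specification (edge in nm)."""

    edge_nm: float

    def __post_init__(self) -> None:
        if not self.edge_nm > 0:
            raise ValueError(f"edge must be positive, got {self.edge_nm}")


@dataclass(frozen=True)
class SystemComposition:
    """Molecule counts of a solvated simulation box."""

    protein: int = 1
    water: int = 0
    na: int = 0
    cl: int = 0
    cofactor: int = 0

    def __post_init__(self) -> None:
        for name in ("protein", "water", "na", "cl", "cofactor"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} count must be a non-negative integer")

    def as_dict(self) -> dict[str, int]:
        return {k: int(getattr(self, k))
                for k in ("protein", "water", "na", "cl", "cofactor")}


@dataclass(frozen=True)
class PairedObservation:
    """One calculated-vs-experimental pair for a thermodynamic
    quantity ('dH' | 'dCp' | 'dG')."""

    system_id: str
    quantity: str
    experimental: float
    calculated: float
    exp_se: float = float("nan")
    calc_se: float = float("nan")
    units: str = ""
    outlier: bool = False

    def __post_init__(self) -> None:
        if self.quantity not in ("dH", "dCp", "dG"):
            raise ValueError(f"unknown quantity {self.quantity!r}")


@dataclass(frozen=True)
class FitReport:
    """OLS fit of calculated (y) on experimental (x) values."""

    slope: float
    intercept: float
    r_squared: float
    n_used: int
    excluded: tuple[str, ...] = ()
    se_slope: float = float("nan")
    se_intercept: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_used < 2:
            raise ValueError("a fit needs at least 2 points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
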