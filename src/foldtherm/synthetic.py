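"""Synthetic stand-ins for MD output.

Three generators emulate the statistical structure of the real
pipeline inputs without running any simulation:

* replica enthalpies — per-replica time-averaged enthalpies drawn
  around state means that are linear in temperature, so a prescribed
  dH(T) and dCp are recoverable by the ensemble-averaging + OLS
  pipeline;
* CA-trace chain ensembles — self-avoiding random walks with fixed
  3.8 angstrom virtual bonds and an excluded-volume cutoff, standing
  in for coil-library unfolded ensembles, with enough diameter spread
  to exercise percentile filtering and box sizing;
* Rg drift series — linear drift plus noise for the overcompaction
  check.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import Conformation, ConformationEnsemble

__all__ = [
    "EnthalpyGeneratorSpec",
    "ChainGeneratorSpec",
    "gen_replica_enthalpies",
    "gen_chain_ensemble",
    "gen_rg_series",
]


@dataclass(frozen=True)
class EnthalpyGeneratorSpec:
    """Ground-truth parameters for synthetic replica enthalpies.

    The folded-state box enthalpy is linear in temperature
    (``base_H0 + base_slope * T``, both in kcal/mol terms); the
    unfolded state sits above it by
    ``dH_at_Tref + dCp_true * (T - Tref)``.  Defaults mirror the
    study conditions of the replica workflow: 40 folded and 100
    unfolded replicas per temperature, three temperatures spanning
    ~30 K around the melting region, noisier unfolded boxes.
    """

    dH_at_Tref: float = 80.0
    dCp_true: float = 1.5
    Tref: float = 320.0
    base_H0: float = -1.2e5
    base_slope: float = 50.0
    sd_folded: float = 20.0
    sd_unfolded: float = 60.0
    n_folded: int = 40
    n_unfolded: int = 100
    temperatures: tuple[float, ...] = (310.0, 320.0, 330.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_folded, self.sd_unfolded) < 0:
            raise ValueError("noise SDs must be non-negative")
        if min(self.n_folded, self.n_unfolded) < 1:
            raise ValueError("replica counts must be >= 1")
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ValueError("temperatures must be distinct")

    def true_dH(self, T: float) -> float:
        return self.dH_at_Tref + self.dCp_true * (T - self.Tref)

    def base_H(self, T: float) -> float:
        return self.base_H0 + self.base_slope * T


def gen_replica_enthalpies(spec: EnthalpyGeneratorSpec):
    """Draw per-replica mean enthalpies for folded and unfolded states.

    Returns ``(samples, truth)`` where ``samples`` maps
    ``(state_label, T)`` to an array of replica means and ``truth``
    records the generating parameters including the exact
    ``true_dH`` per temperature.
    """
    rng = np.random.default_rng(spec.seed)
    samples: dict[tuple[str, float], np.ndarray] = {}
    for T in spec.temperatures:
        base = spec.base_H(T)
        samples[("folded", T)] = rng.normal(
            base, spec.sd_folded, spec.n_folded)
        samples[("unfolded", T)] = rng.normal(
            base + spec.true_dH(T), spec.sd_unfolded, spec.n_unfolded)
    truth = {
        "dH_at_Tref": spec.dH_at_Tref,
        "dCp_true": spec.dCp_true,
        "Tref": spec.Tref,
        "true_dH": {T: spec.true_dH(T) for T in spec.temperatures},
    }
    return samples, truth


@dataclass(frozen=True)
class ChainGeneratorSpec:
    """Self-avoiding CA-trace chain ensemble parameters.

    ``bond_length`` is the fixed consecutive CA-CA distance (3.8
    angstrom, the trans-peptide virtual bond); ``min_separation``
    is the excluded-volume cutoff between non-adjacent residues.
    """

    n_residues: int = 40
    n_models: int = 100
    bond_length: float = 3.8
    min_separation: float = 4.0
    seed: int = 0
    max_attempts_per_step: int = 200

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.n_models < 1:
            raise ValueError("need at least 1 model")


def _random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _grow_chain(spec: ChainGeneratorSpec, rng) -> np.ndarray:
    """Grow one self-avoiding walk; raises RuntimeError when the
    rejection budget is exhausted (dead end)."""
    coords = np.zeros((spec.n_residues, 3))
    for i in range(1, spec.n_residues):
        placed = False
        steps = _random_unit_vectors(rng, spec.max_attempts_per_step)
        for step in steps:
            candidate = coords[i - 1] + spec.bond_length * step
            if i >= 2:
                d = np.linalg.norm(coords[: i - 1] - candidate, axis=1)
                if d.min() < spec.min_separation:
                    continue
            coords[i] = candidate
            placed = True
            break
        if not placed:
            raise RuntimeError("chain growth hit a dead end")
    return coords


def gen_chain_ensemble(spec: ChainGeneratorSpec) -> ConformationEnsemble:
    """Generate a CA-only self-avoiding chain ensemble.

    Dead-end walks are retried with fresh randomness; a model that
    cannot be grown within the attempt budget raises, suggesting a
    smaller ``n_residues``.
    """
    rng = np.random.default_rng(spec.seed)
    models = []
    for m in range(spec.n_models):
        coords = None
        for _ in range(50):  # chain-level regrow budget
            try:
                coords = _grow_chain(spec, rng)
                break
            except RuntimeError:
                continue
        if coords is None:
            raise RuntimeError(
                "could not grow a self-avoiding chain within the attempt "
                "budget; try fewer residues or a smaller min_separation")
        models.append(Conformation(model_id=m + 1, coords=coords))
    return ConformationEnsemble(models)


def gen_rg_series(initial_rg: float, relative_drift: float,
                  n_points: int = 100, noise_sd: float = 0.0,
                  seed: int = 0, t_end: float = 2.0):
    """Synthetic (time, Rg) trajectory with a prescribed relative
    linear drift over the window plus Gaussian noise.

    ``relative_drift = -0.2`` shrinks Rg by 20% across the window.
    Times run from 0 to ``t_end`` (ns).
    """
    if n_points < 2:
        raise ValueError("need at least two points")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_end, n_points)
    rg = initial_rg * (1.0 + relative_drift * t / t_end)
    if noise_sd > 0:
        rg = rg + rng.normal(0.0, noise_sd, n_points)
    return list(zip(t.tolist(), rg.tolist()))
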