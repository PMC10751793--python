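"""Unfolded-ensemble geometry: diameters, extended-conformer
filtering, simulation-box sizing, radius of gyration and box
composition matching.

Unfolded ensembles dictate the simulation box: the box edge must
accommodate the most elongated conformer plus a solvent margin, so
the most extended conformers (~10% by default) are removed before
box sizing to keep boxes (and solvent noise) manageable.
Coordinates are handled in angstrom; box edges are reported in nm.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .models import BoxSpec, Conformation, ConformationEnsemble, SystemComposition

A_PER_NM = 10.0

__all__ = [
    "molecular_diameter",
    "filter_extended",
    "box_from_ensemble",
    "radius_of_gyration",
    "composition_match",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "ensemble_report",
]


def molecular_diameter(c: Conformation, method: str = "auto") -> float:
    """Maximum pairwise inter-atom distance (angstrom).

    ``method="brute"`` computes all O(n^2) pairs (the reference
    definition); ``"hull"`` restricts the pair search to convex-hull
    vertices, which contains the farthest pair and is exact;
    ``"auto"`` picks by size.  Degenerate point sets (single atom,
    collinear) fall back to brute force.
    """
    x = c.coords
    n = x.shape[0]
    if n == 1:
        return 0.0
    if method not in ("auto", "brute", "hull"):
        raise ValueError(f"unknown method {method!r}")
    if method == "hull" or (method == "auto" and n > 64):
        try:
            hull = ConvexHull(x)
            x = x[hull.vertices]
        except QhullError:
            pass  # flat/collinear input: brute force below
    return float(pdist(x).max())


def filter_extended(e: ConformationEnsemble, mode: str = "percentile",
                    value: float = 10.0):
    """Remove the most extended conformers from an ensemble.

    Parameters
    ----------
    mode : {"percentile", "cutoff"}
        ``"percentile"`` removes models whose diameter is strictly
        above the (100 - value)-th percentile (nearest-rank), so
        ``value=10`` trims roughly the top 10%; ties at the threshold
        are kept, so an ensemble of identical conformers is never
        decimated.  ``"cutoff"`` removes diameters strictly above a
        fixed cutoff in angstrom.

    Returns
    -------
    kept : ConformationEnsemble
    removed_ids : list of int
    """
    diams = e.diameters()
    n = len(e)
    if mode == "percentile":
        if not 0 < value < 100:
            raise ValueError("percentile value must lie in (0, 100)")
        # nearest-rank percentile of the kept fraction
        k = int(np.ceil((100.0 - value) / 100.0 * n))
        k = min(max(k, 1), n)
        threshold = float(np.sort(diams)[k - 1])
    elif mode == "cutoff":
        if value <= 0:
            raise ValueError("cutoff must be positive (angstrom)")
        threshold = float(value)
    else:
        raise ValueError(f"mode must be 'percentile' or 'cutoff', got {mode!r}")
    keep_mask = diams <= threshold
    kept_models = [m for m, k in zip(e.models, keep_mask) if k]
    removed_ids = [m.model_id for m, k in zip(e.models, keep_mask) if not k]
    if not kept_models:
        raise ValueError("filter removed every model")
    kept = ConformationEnsemble(kept_models)
    kept._diameters = diams[keep_mask]
    return kept, removed_ids


def box_from_ensemble(e: ConformationEnsemble, margin_nm: float = 1.0) -> BoxSpec:
    """Cubic box sized from the most elongated conformer.

    Edge = max diameter + 2 * margin, the margin being the minimum
    protein-to-edge distance (default 1 nm) applied on both sides.
    """
    if margin_nm < 0:
        raise ValueError("margin must be non-negative")
    dmax_nm = float(e.diameters().max()) / A_PER_NM
    edge = dmax_nm + 2.0 * margin_nm
    if edge <= 0:
        raise ValueError("degenerate box: zero diameter and zero margin")
    return BoxSpec(edge_nm=edge)


def radius_of_gyration(c: Conformation) -> float:
    """Mass-weighted radius of gyration about the centre of mass
    (angstrom); unit masses are assumed when none are stored."""
    x = c.coords
    m = c.masses if c.masses is not None else np.ones(x.shape[0])
    w = m / m.sum()
    com = w @ x
    return float(np.sqrt(np.sum(w * np.sum((x - com) ** 2, axis=1))))


def composition_match(folded: SystemComposition,
                      unfolded: SystemComposition):
    """Check that folded and unfolded boxes hold identical molecule
    counts (enthalpy differences are only meaningful then).

    Returns ``(passed, deltas)`` where ``deltas`` maps species to
    unfolded-minus-folded count differences.
    """
    deltas = {k: unfolded.as_dict()[k] - v
              for k, v in folded.as_dict().items()}
    return all(d == 0 for d in deltas.values()), deltas


# ---------------------------------------------------------------------------
# PDB I/O (multi-model NMR-style ensembles via biotite)

def _stack_to_ensemble(stack) -> ConformationEnsemble:
    models = []
    try:
        masses = np.array([struc.info.mass(el) if el else 0.0
                           for el in stack.element], dtype=float)
        if not np.all(masses > 0):
            masses = None
    except Exception:
        masses = None
    names = tuple(stack.atom_name) if stack.atom_name is not None else None
    for i in range(stack.stack_depth()):
        models.append(Conformation(
            model_id=i + 1, coords=np.asarray(stack.coord[i], dtype=float),
            masses=masses, atom_names=names))
    return ConformationEnsemble(models)


def read_pdb_ensemble(path, ca_only: bool = False) -> ConformationEnsemble:
    """Read a multi-model PDB file (MODEL/ENDMDL records) into an
    ensemble; ``ca_only`` restricts to alpha carbons."""
    f = pdb.PDBFile.read(str(path))
    stack = f.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    if ca_only:
        stack = stack[:, stack.atom_name == "CA"]
        if stack.array_length() == 0:
            raise ValueError("no CA atoms found")
    return _stack_to_ensemble(stack)


def read_pdb_directory(directory, pattern: str = "*.pdb",
                       ca_only: bool = False) -> ConformationEnsemble:
    """Read a directory of single-model PDB files as one ensemble."""
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise ValueError(f"no files matching {pattern!r} in {directory}")
    models = []
    for i, p in enumerate(paths):
        e = read_pdb_ensemble(p, ca_only=ca_only)
        for c in e.models:
            models.append(Conformation(model_id=i + 1, coords=c.coords,
                                       masses=c.masses,
                                       atom_names=c.atom_names))
    return ConformationEnsemble(models)


def write_pdb_ensemble(e: ConformationEnsemble, path,
                       atom_name: str = "CA", res_name: str = "ALA",
                       element: str = "C") -> None:
    """Write an ensemble as a multi-model PDB file.

    Atom metadata defaults to a CA-trace representation, matching the
    synthetic chain generator output.
    """
    n_atoms = e.models[0].n_atoms
    arrays = []
    for c in e.models:
        if c.n_atoms != n_atoms:
            raise ValueError("all models must share the atom count")
        atoms = struc.AtomArray(n_atoms)
        atoms.coord = c.coords
        atoms.chain_id = np.full(n_atoms, "A")
        atoms.res_id = np.arange(1, n_atoms + 1)
        atoms.res_name = np.full(n_atoms, res_name)
        if c.atom_names is not None:
            atoms.atom_name = np.array(c.atom_names)
        else:
            atoms.atom_name = np.full(n_atoms, atom_name)
        atoms.element = np.full(n_atoms, element)
        arrays.append(atoms)
    f = pdb.PDBFile()
    f.set_structure(struc.stack(arrays))
    f.write(str(path))


def ensemble_report(e: ConformationEnsemble, kept_ids=None):
    """Per-model diameter/Rg table as a pandas DataFrame
    (model_id, diameter_A, rg_A, kept)."""
    import pandas as pd

    kept = set(m.model_id for m in e.models) if kept_ids is None else set(kept_ids)
    return pd.DataFrame({
        "model_id": [m.model_id for m in e.models],
        "diameter_A": e.diameters(),
        "rg_A": e.radii_of_gyration(),
        "kept": [m.model_id in kept for m in e.models],
    })


def write_composition(comp: SystemComposition, path) -> None:
    Path(path).write_text(json.dumps(comp.as_dict(), indent=2) + "\n")


def read_composition(path) -> SystemComposition:
    return SystemComposition(**{k: int(v)
                                for k, v in json.loads(Path(path).read_text()).items()})
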