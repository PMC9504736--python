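"""Shrake-Rupley solvent-accessible surface area.

Each heavy atom gets a deterministic quasi-uniform shell of test points
(golden-spiral construction) on its solvent-expanded sphere of radius
``r_atom + probe``.  A point is accessible iff it lies outside every other
atom's expanded sphere; the atom's area is the accessible fraction of
``4 pi (r_atom + probe)^2``.  Neighbor search uses a KD-tree with cutoff
``r_i + r_j + 2 probe``.  There is no randomness anywhere, so results are
exactly reproducible and rigid-motion invariant to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom

__all__ = ["SASAResult", "RADII_SETS", "shrake_rupley", "golden_spiral_points"]

# Chothia-type protein radii (A); the single carbon radius 1.87 is used for
# all carbons (the aromatic 1.76 refinement is deliberately not split out,
# since inputs carry element symbols, not chemical types).
RADII_SETS: dict[str, dict[str, float]] = {
    "chothia": {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90,
                "H": 1.00, "D": 1.00},
    "bondi": {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
              "H": 1.20, "D": 1.20, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98},
}

DEFAULT_PROBE = 1.4  # water probe, A
DEFAULT_N_POINTS = 960


@dataclass
class SASAResult:
    per_atom: np.ndarray  # area per input atom, A^2
    per_residue: dict[tuple, float] = field(default_factory=dict)
    total: float = 0.0
    probe_radius: float = DEFAULT_PROBE
    n_points: int = DEFAULT_N_POINTS
    radii_set_name: str = "chothia"


def golden_spiral_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points by the golden-spiral construction."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _radius(element: str, radii: dict[str, float], default: float | None) -> float:
    r = radii.get(element) or radii.get(element.upper())
    if r is None:
        if default is not None:
            return default
        raise KeyError(f"no van der Waals radius for element {element!r} and no default given")
    return r


def shrake_rupley(
    atoms: list[Atom],
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: dict[str, float] | str = "chothia",
    default_radius: float | None = None,
    residue_keys: list[tuple] | None = None,
    include_hydrogens: bool = False,
) -> SASAResult:
    """SASA of an atom collection.

    Parameters mirror the classical algorithm: ``probe_radius`` (default
    1.4 A, water), ``n_points`` test points per atom (default 960) and a
    ``radii`` set name or element -> radius map.  ``residue_keys``, when
    given (one key per atom), enables the per-residue breakdown.  Hydrogens
    are excluded unless ``include_hydrogens`` is set.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_points < 100:
        raise ValueError("n_points must be at least 100")
    radii_name = radii if isinstance(radii, str) else "custom"
    radii_map = RADII_SETS[radii] if isinstance(radii, str) else radii

    mask = [True] * len(atoms) if include_hydrogens else [not a.is_hydrogen for a in atoms]
    idx = [i for i, m in enumerate(mask) if m]
    if not idx:
        raise ValueError("no heavy atoms to compute SASA on")
    coords = np.array([atoms[i].coords for i in idx], dtype=float)
    expanded = np.array(
        [_radius(atoms[i].element, radii_map, default_radius) + probe_radius for i in idx]
    )

    sphere = golden_spiral_points(n_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    per_atom_sel = np.zeros(len(idx))
    for k in range(len(idx)):
        pts = coords[k] + expanded[k] * sphere
        neighbors = tree.query_ball_point(coords[k], r=expanded[k] + max_r)
        neighbors = [j for j in neighbors if j != k
                     and np.linalg.norm(coords[j] - coords[k]) < expanded[k] + expanded[j]]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        per_atom_sel[k] = accessible.sum() / n_points * 4.0 * np.pi * expanded[k] ** 2

    per_atom = np.zeros(len(atoms))
    per_atom[idx] = per_atom_sel

    per_residue: dict[tuple, float] = {}
    if residue_keys is not None:
        if len(residue_keys) != len(atoms):
            raise ValueError("residue_keys must align with atoms")
        for i, key in enumerate(residue_keys):
            per_residue[key] = per_residue.get(key, 0.0) + float(per_atom[i])

    return SASAResult(
        per_atom=per_atom,
        per_residue=per_residue,
        total=float(per_atom.sum()),
        probe_radius=probe_radius,
        n_points=n_points,
        radii_set_name=radii_name,
    )


def pocket_sasa(pocket, **kwargs) -> SASAResult:
    """SASA of a pocket's heavy atoms in isolation (the fragment on its own)."""
    atoms = []
    keys = []
    for res in pocket.residues:
        for a in res.heavy_atoms():
            atoms.append(a)
            keys.append(res.key)
    return shrake_rupley(atoms, residue_keys=keys, **kwargs)


def pocket_sasa_in_context(pocket, **kwargs) -> SASAResult:
    """Per-residue SASA of the pocket computed in the context of the full
    parent chain (occlusion by residues outside the fragment included); the
    returned total sums over pocket residues only."""
    atoms = []
    keys = []
    pocket_keys = {r.key for r in pocket.residues}
    for res in pocket.parent.chains[pocket.chain_id]:
        for a in res.heavy_atoms():
            atoms.append(a)
            keys.append(res.key)
    full = shrake_rupley(atoms, residue_keys=keys, **kwargs)
    per_residue = {k: v for k, v in full.per_residue.items() if k in pocket_keys}
    return SASAResult(
        per_atom=full.per_atom,
        per_residue=per_residue,
        total=float(sum(per_residue.values())),
        probe_radius=full.probe_radius,
        n_points=full.n_points,
        radii_set_name=full.radii_set_name,
    )
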