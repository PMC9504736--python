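"""Protein-ligand interaction profiles.

For one pocket + ligand pair this produces the tabular interaction "sweep":
geometric hydrogen bonds in both directions (protein donor or ligand donor),
the hydrophobic contact count under the <10 A minimum heavy-atom distance
rule (nonpolar residues only), and the binding locus - the handful of pocket
residues closest to the ligand, whatever their polarity, credited with
positioning and retaining it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .geometry import (
    DEFAULT_CONTACT_CUTOFF,
    DEFAULT_HB_ANGLE,
    DEFAULT_HB_DISTANCE,
    HBond,
    POLARITY_CLASSES,
    _acceptors,
    _angle_deg,
    _donors,
)
from .structure import LigandMolecule, PocketModel, Residue

__all__ = [
    "LigandProfile",
    "ligand_hbonds",
    "hydrophobic_contacts",
    "binding_locus",
    "interaction_sweep",
    "build_profile",
]

LIGAND_BOND_MAX = 1.8  # A; ligand heavy atoms closer than this are bonded


@dataclass
class LigandProfile:
    ligand: LigandMolecule
    pocket: PocketModel
    hbonds: list[HBond] = field(default_factory=list)
    hydrophobic_contacts: list[tuple[Residue, float]] = field(default_factory=list)
    residue_min_distances: dict[tuple, float] = field(default_factory=dict)
    locus_residues: list[Residue] = field(default_factory=list)
    cutoff: float = DEFAULT_CONTACT_CUTOFF

    @property
    def n_hb(self) -> int:
        return len(self.hbonds)

    @property
    def n_hydrophobic(self) -> int:
        return len(self.hydrophobic_contacts)


def _ligand_antecedent(atom, ligand: LigandMolecule):
    """Nearest bonded heavy atom of the ligand (None for an isolated atom)."""
    best, best_d = None, LIGAND_BOND_MAX
    for other in ligand.heavy_atoms():
        if other is atom:
            continue
        d = float(np.linalg.norm(other.coords - atom.coords))
        if d < best_d:
            best, best_d = other, d
    return best


def ligand_hbonds(
    pocket: PocketModel | list[Residue],
    ligand: LigandMolecule,
    d_max: float = DEFAULT_HB_DISTANCE,
    angle_min: float = DEFAULT_HB_ANGLE,
) -> list[HBond]:
    """Protein-ligand hydrogen bonds under the geometric criteria.

    Ligand typing is by element: N and O atoms act as both donors and
    acceptors (nitrile nitrogens are thereby acceptors); protein donors and
    acceptors follow the standard residue templates.  The angle criterion is
    evaluated at the donor; a ligand donor with no bonded heavy atom within
    1.8 A has no antecedent and passes the angle test by default.
    """
    residues = pocket.residues if isinstance(pocket, PocketModel) else list(pocket)
    lig_polar = [a for a in ligand.heavy_atoms() if a.element in ("N", "O")]
    bonds: list[HBond] = []
    seen_pairs: set[frozenset] = set()  # one bond per atom pair, whichever direction

    # protein donor -> ligand acceptor
    for res in residues:
        for datom, dante in _donors(res):
            for aatom in lig_polar:
                dist = float(np.linalg.norm(datom.coords - aatom.coords))
                if dist > d_max:
                    continue
                ang = _angle_deg(dante.coords, datom.coords, aatom.coords)
                if ang < angle_min:
                    continue
                pair = frozenset((id(datom), id(aatom)))
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
                bonds.append(HBond(donor_atom=datom, acceptor_atom=aatom,
                                   donor_residue=res, acceptor_residue=None,
                                   distance=dist, angle=ang))
    # ligand donor -> protein acceptor (nitrogens and oxygens donate)
    for datom in lig_polar:
        dante = _ligand_antecedent(datom, ligand)
        for res in residues:
            for aatom in _acceptors(res):
                dist = float(np.linalg.norm(datom.coords - aatom.coords))
                if dist > d_max:
                    continue
                if dante is not None:
                    ang = _angle_deg(dante.coords, datom.coords, aatom.coords)
                    if ang < angle_min:
                        continue
                else:
                    ang = float("nan")
                pair = frozenset((id(datom), id(aatom)))
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
                bonds.append(HBond(donor_atom=datom, acceptor_atom=aatom,
                                   donor_residue=None, acceptor_residue=res,
                                   distance=dist, angle=ang))
    return bonds


def residue_ligand_distances(pocket: PocketModel | list[Residue], ligand: LigandMolecule) -> dict:
    """Minimum heavy-atom distance from every pocket residue to the ligand."""
    residues = pocket.residues if isinstance(pocket, PocketModel) else list(pocket)
    lig = ligand.heavy_coords()
    out = {}
    for res in residues:
        rc = res.heavy_coords()
        out[res.key] = float(np.linalg.norm(rc[:, None, :] - lig[None, :, :], axis=2).min())
    return out


def hydrophobic_contacts(
    pocket: PocketModel | list[Residue],
    ligand: LigandMolecule,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    polarity_table: dict[str, str] | None = None,
) -> list[tuple[Residue, float]]:
    """Nonpolar pocket residues whose minimum heavy-atom distance to any
    ligand heavy atom is below ``cutoff`` (default 10 A), with that distance."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    residues = pocket.residues if isinstance(pocket, PocketModel) else list(pocket)
    table = polarity_table or POLARITY_CLASSES
    lig = ligand.heavy_coords()
    out = []
    for res in residues:
        if table.get(res.name) != "nonpolar":
            continue
        rc = res.heavy_coords()
        d = float(np.linalg.norm(rc[:, None, :] - lig[None, :, :], axis=2).min())
        if d < cutoff:
            out.append((res, d))
    return out


def binding_locus(profile: "LigandProfile", k: int = 4) -> list[Residue]:
    """The k pocket residues nearest the ligand by minimum heavy-atom
    distance, polar and charged residues included; ties break toward the
    lower residue number."""
    dists = profile.residue_min_distances
    residues = profile.pocket.residues
    if k > len(residues):
        warnings.warn(f"k={k} exceeds pocket size {len(residues)}; returning all residues")
        k = len(residues)
    ranked = sorted(residues, key=lambda r: (dists[r.key], r.number))
    return ranked[:k]


def build_profile(
    pocket: PocketModel,
    ligand: LigandMolecule,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    d_max: float = DEFAULT_HB_DISTANCE,
    angle_min: float = DEFAULT_HB_ANGLE,
    locus_k: int = 4,
    polarity_table: dict[str, str] | None = None,
) -> LigandProfile:
    """Assemble the full interaction profile for one pocket + ligand pair."""
    profile = LigandProfile(
        ligand=ligand,
        pocket=pocket,
        hbonds=ligand_hbonds(pocket, ligand, d_max=d_max, angle_min=angle_min),
        hydrophobic_contacts=hydrophobic_contacts(pocket, ligand, cutoff=cutoff,
                                                  polarity_table=polarity_table),
        residue_min_distances=residue_ligand_distances(pocket, ligand),
        cutoff=cutoff,
    )
    profile.locus_residues = binding_locus(profile, k=locus_k)
    return profile


def interaction_sweep(profile: LigandProfile) -> pd.DataFrame:
    """One row per interaction (hydrogen bond or hydrophobic contact), sorted
    by type then distance - the tabular equivalent of a 2D interaction
    diagram."""
    rows = []
    for hb in profile.hbonds:
        res = hb.donor_residue or hb.acceptor_residue
        rows.append({
            "type": "HB",
            "residue": res.label if res is not None else "LIG",
            "atoms": f"{hb.donor_atom.name}->{hb.acceptor_atom.name}",
            "distance": round(hb.distance, 3),
        })
    for res, d in profile.hydrophobic_contacts:
        rows.append({"type": "hydrophobic", "residue": res.label, "atoms": "", "distance": round(d, 3)})
    frame = pd.DataFrame(rows, columns=["type", "residue", "atoms", "distance"])
    return frame.sort_values(["type", "distance"], kind="stable").reset_index(drop=True)
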