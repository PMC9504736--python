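"""Ligand interaction profiles on planted toy complexes."""

import numpy as np
import pytest

from pocketprofiler.ligand import (
    binding_locus,
    build_profile,
    hydrophobic_contacts,
    interaction_sweep,
    ligand_hbonds,
)
from pocketprofiler.structure import extract_ligand, parse_pdb, select_pocket, write_pdb
from pocketprofiler.synthetic import LigandPlan, PlantedHBond, SyntheticSpec, toy_complex

NONPOLAR = ["LEU", "VAL", "ALA", "GLY"]
POLAR = ["SER", "ASN", "ASP", "ARG"]


def _complex_through_pdb(spec: SyntheticSpec):
    """Round-trip the fixture through the PDB reader, then split pocket/ligand."""
    model = parse_pdb(write_pdb(toy_complex(spec)))
    pocket = select_pocket(model, "A", 1, spec.n_residues)
    ligand = extract_ligand(model, "LIG")
    return pocket, ligand


def test_four_planted_residues_within_cutoff():
    names = NONPOLAR + POLAR + NONPOLAR[:2]
    spec = SyntheticSpec(
        n_residues=10, residue_names=names,
        ligand_plan=LigandPlan(n_atoms=5, near=[(0, 6.0), (1, 7.5), (2, 8.5), (3, 9.5)]),
        seed=1,
    )
    pocket, ligand = _complex_through_pdb(spec)
    contacts = hydrophobic_contacts(pocket, ligand, cutoff=10.0)
    assert len(contacts) == 4
    by_res = {r.number: d for r, d in contacts}
    assert by_res[1] == pytest.approx(6.0, abs=0.03)
    assert by_res[4] == pytest.approx(9.5, abs=0.03)


def test_vanishing_cutoff_gives_no_contacts():
    spec = SyntheticSpec(n_residues=6, residue_names=NONPOLAR + POLAR[:2],
                         ligand_plan=LigandPlan(near=[(0, 5.0)]), seed=2)
    pocket, ligand = _complex_through_pdb(spec)
    assert hydrophobic_contacts(pocket, ligand, cutoff=0.1) == []


def test_ligand_moved_far_away_has_empty_profile():
    spec = SyntheticSpec(n_residues=6, residue_names=NONPOLAR + POLAR[:2],
                         ligand_plan=LigandPlan(near=[(0, 5.0)]), seed=3)
    pocket, ligand = _complex_through_pdb(spec)
    for a in ligand.atoms:
        a.coords = a.coords + np.array([500.0, 0.0, 0.0])
    assert hydrophobic_contacts(pocket, ligand) == []
    assert ligand_hbonds(pocket, ligand) == []


def test_planted_hbond_found_exactly():
    spec = SyntheticSpec(
        n_residues=6, residue_names=POLAR + NONPOLAR[:2],
        ligand_plan=LigandPlan(n_atoms=4, elements=["C"] * 4),
        planted_hbonds=[PlantedHBond(residue_index=2, protein_atom="O",
                                     ligand_is_donor=True, distance=2.9, angle=170.0)],
        seed=4,
    )
    pocket, ligand = _complex_through_pdb(spec)
    bonds = ligand_hbonds(pocket, ligand)
    assert len(bonds) == 1
    assert bonds[0].acceptor_residue.number == 3
    assert bonds[0].distance == pytest.approx(2.9, abs=1e-3)


def test_protein_donor_direction_also_detected():
    spec = SyntheticSpec(
        n_residues=6, residue_names=["SER"] + POLAR[1:] + NONPOLAR[:2],
        ligand_plan=LigandPlan(n_atoms=4, elements=["C"] * 4),
        planted_hbonds=[PlantedHBond(residue_index=0, protein_atom="OG",
                                     ligand_is_donor=False, distance=3.0, angle=150.0)],
        seed=5,
    )
    pocket, ligand = _complex_through_pdb(spec)
    bonds = ligand_hbonds(pocket, ligand)
    assert len(bonds) == 1
    assert bonds[0].donor_residue.number == 1
    assert bonds[0].donor_atom.name == "OG"


def test_locus_is_nearest_residues_any_polarity():
    spec = SyntheticSpec(
        n_residues=8, residue_names=["ASP", "LEU", "VAL", "SER", "GLY", "ALA", "ASN", "ARG"],
        ligand_plan=LigandPlan(near=[(0, 4.0), (1, 5.0), (2, 6.0), (3, 7.0), (4, 8.0)]),
        seed=6,
    )
    pocket, ligand = _complex_through_pdb(spec)
    profile = build_profile(pocket, ligand)
    locus = [r.number for r in profile.locus_residues]
    assert locus == [1, 2, 3, 4]  # charged ASP ranks first: pool is polarity-blind
    top = binding_locus(profile, k=1)
    assert top[0].name == "ASP"


def test_locus_k_larger_than_pocket_warns_and_returns_all():
    spec = SyntheticSpec(n_residues=4, residue_names=NONPOLAR,
                         ligand_plan=LigandPlan(near=[(0, 5.0)]), seed=7)
    pocket, ligand = _complex_through_pdb(spec)
    profile = build_profile(pocket, ligand)
    with pytest.warns(UserWarning):
        assert len(binding_locus(profile, k=10)) == 4


def test_cutoff_monotonicity():
    spec = SyntheticSpec(
        n_residues=8, residue_names=NONPOLAR * 2,
        ligand_plan=LigandPlan(near=[(i, 4.0 + 1.3 * i) for i in range(6)]), seed=8)
    pocket, ligand = _complex_through_pdb(spec)
    counts = [len(hydrophobic_contacts(pocket, ligand, cutoff=c))
              for c in (2.0, 5.0, 8.0, 11.0)]
    assert counts == sorted(counts)


def test_planted_recovery_on_100_randomized_complexes():
    """Generator-specified hydrogen-bond and hydrophobic-contact counts are
    recovered exactly, and the sweep row count always equals their sum."""
    rng = np.random.default_rng(99)
    for seed in range(100):
        n_near = int(rng.integers(0, 5))
        n_hb = int(rng.integers(0, 3))
        near = [(i, float(rng.uniform(4.0, 9.3))) for i in range(n_near)]
        hbs = [PlantedHBond(residue_index=4 + j, protein_atom="O", ligand_is_donor=True,
                            distance=float(rng.uniform(2.7, 3.3)),
                            angle=float(rng.uniform(130.0, 178.0)))
               for j in range(n_hb)]
        # CYS hosts the planted bonds: polar class, but no side-chain N/O that
        # could form incidental geometry with the planted partner atoms
        names = NONPOLAR + ["CYS", "CYS", "ASP", "ARG", "SER", "ASN"]
        spec = SyntheticSpec(n_residues=10, residue_names=names,
                             ligand_plan=LigandPlan(n_atoms=4, elements=["C"] * 4, near=near),
                             planted_hbonds=hbs, seed=seed)
        pocket, ligand = _complex_through_pdb(spec)
        profile = build_profile(pocket, ligand)
        assert profile.n_hydrophobic == n_near, f"seed {seed}"
        assert profile.n_hb == n_hb, f"seed {seed}"
        sweep = interaction_sweep(profile)
        assert len(sweep) == profile.n_hb + profile.n_hydrophobic


def test_empty_profile_sweep_is_header_only():
    spec = SyntheticSpec(n_residues=4, residue_names=POLAR, ligand_plan=LigandPlan(), seed=10)
    pocket, ligand = _complex_through_pdb(spec)
    sweep = interaction_sweep(build_profile(pocket, ligand))
    assert list(sweep.columns) == ["type", "residue", "atoms", "distance"]
    assert len(sweep) == 0


def test_locus_members_appear_among_interactions():
    spec = SyntheticSpec(
        n_residues=8, residue_names=NONPOLAR * 2,
        ligand_plan=LigandPlan(near=[(i, 5.0 + i) for i in range(5)]), seed=11)
    pocket, ligand = _complex_through_pdb(spec)
    profile = build_profile(pocket, ligand)
    interacting = {r.number for r, _ in profile.hydrophobic_contacts}
    interacting |= {b.acceptor_residue.number for b in profile.hbonds if b.acceptor_residue}
    interacting |= {b.donor_residue.number for b in profile.hbonds if b.donor_residue}
    for r in profile.locus_residues:
        assert r.number in interacting
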