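"""Ground-truth properties of the synthetic structure generator."""

import numpy as np
import pytest

from pocketprofiler.geometry import nonpolar_contact_network
from pocketprofiler.structure import parse_pdb, write_pdb
from pocketprofiler.synthetic import (
    LigandPlan,
    PlacementError,
    SyntheticSpec,
    ideal_helix,
    ideal_strand_pair,
    residues_to_model,
    toy_complex,
)


def test_helix_ca_distance_matches_closed_form():
    radius, rise, twist = 2.3, 1.5, 100.0
    expected = np.sqrt((2 * radius * np.sin(np.radians(twist / 2))) ** 2 + rise**2)
    helix = ideal_helix(20, radius=radius, rise=rise, twist=twist)
    ca = np.array([r.atom("CA").coords for r in helix])
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    np.testing.assert_allclose(d, expected, atol=1e-9)
    assert expected == pytest.approx(3.83, abs=0.01)


def test_small_twist_approaches_linear_rise():
    n = 30
    helix = ideal_helix(n, twist=360.0 / (10 * n))
    ca = np.array([r.atom("CA").coords for r in helix])
    dz = np.diff(ca[:, 2])
    np.testing.assert_allclose(dz, 1.5, atol=1e-9)
    span = np.linalg.norm(ca[-1] - ca[0])
    assert span > 0.98 * 1.5 * (n - 1)


def test_helix_backbone_complete():
    for res in ideal_helix(8):
        assert {a.name for a in res.atoms} == {"N", "CA", "C", "O"}


def test_helix_rejects_empty():
    with pytest.raises(ValueError):
        ideal_helix(0)


def test_seeded_determinism_byte_identical():
    spec = SyntheticSpec(n_residues=12, ligand_plan=LigandPlan(near=[(0, 6.0)]),
                         planted_contacts=[((2, 5), 7.7), ((5, 8), 8.3)],
                         noise_sigma=0.1, seed=77)
    a = write_pdb(toy_complex(spec))
    b = write_pdb(toy_complex(spec))
    assert a == b
    other = write_pdb(toy_complex(SyntheticSpec(**{**spec.__dict__, "seed": 78})))
    assert other != a


def test_planted_centroid_distances_hit_targets():
    pairs = [((0, 3), 7.7), ((3, 6), 8.3), ((0, 6), 9.1), ((2, 8), 6.0)]
    spec = SyntheticSpec(n_residues=10, residue_names=["LEU"] * 10,
                         planted_contacts=pairs, seed=5)
    model = toy_complex(spec)
    residues = model.chains["A"]
    for (i, j), d in pairs:
        got = np.linalg.norm(residues[i].sidechain_centroid() - residues[j].sidechain_centroid())
        assert got == pytest.approx(d, abs=0.05)


def test_infeasible_triangle_raises():
    spec = SyntheticSpec(n_residues=4, residue_names=["LEU"] * 4,
                         planted_contacts=[((0, 1), 2.0), ((1, 2), 2.0), ((0, 2), 10.0)],
                         seed=0)
    with pytest.raises(PlacementError):
        toy_complex(spec)


def test_element_plan_lengths_must_sum():
    with pytest.raises(ValueError):
        SyntheticSpec(n_residues=10, element_plan=[("H", 4), ("C", 3)])


def test_mixture_planted_distances_recover_modes():
    """Contact distances drawn from the stated two-component mixture are
    recovered by the pipeline with both modes in place."""
    from pocketprofiler.geometry import contact_statistics

    rng = np.random.default_rng(7)
    n_pairs = 120
    dists = np.where(rng.integers(0, 2, n_pairs) == 0,
                     rng.normal(7.7, 0.2, n_pairs), rng.normal(8.3, 0.2, n_pairs))
    # partner indices offset by n_pairs so the pairs pass the >=2 sequence-separation rule
    pairs = [((k, k + n_pairs), float(np.clip(d, 6.9, 9.1))) for k, d in enumerate(dists)]
    spec = SyntheticSpec(n_residues=2 * n_pairs, residue_names=["LEU"] * (2 * n_pairs),
                         planted_contacts=pairs, seed=3)
    model = parse_pdb(write_pdb(toy_complex(spec)))
    contacts = nonpolar_contact_network(model.chains["A"], [], cutoff=10.0)
    stats = contact_statistics(contacts)
    # every planted pair is a contact; clusters are spaced beyond the cutoff
    assert stats.n == n_pairs
    assert len(stats.modes) == 2
    assert abs(stats.modes[0] - 7.7) <= 0.25
    assert abs(stats.modes[1] - 8.3) <= 0.25


def test_strand_pair_chains_and_count():
    residues = ideal_strand_pair(6)
    assert len(residues) == 12
    assert {r.chain_id for r in residues} == {"A", "B"}
    model = residues_to_model(residues)
    assert len(model.chains["A"]) == len(model.chains["B"]) == 6


def test_noise_is_bounded():
    spec0 = SyntheticSpec(n_residues=6, seed=1)
    spec1 = SyntheticSpec(n_residues=6, noise_sigma=0.2, seed=1)
    a = toy_complex(spec0).chains["A"]
    b = toy_complex(spec1).chains["A"]
    for ra, rb in zip(a, b):
        for aa, ab in zip(ra.atoms, rb.atoms):
            assert np.all(np.abs(aa.coords - ab.coords) <= 0.4 + 1e-12)  # 2 sigma cap
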