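"""Hydrogen bonds, composition, contact networks and distance statistics."""

import numpy as np
import pytest

from conftest import brute_force_contacts, make_residue, rigid_transform_residues
from pocketprofiler.geometry import (
    classify_residue,
    composition,
    contact_statistics,
    detect_hbonds,
    nonpolar_contact_network,
    residue_distance,
)
from pocketprofiler.secondary import SSElement
from pocketprofiler.structure import Residue
from pocketprofiler.synthetic import RESIDUE_TEMPLATES, _template_residue


def _donor_acceptor_pair(distance: float, angle_deg: float):
    """Residue 1 donates its backbone N (antecedent CA) to residue 10's
    backbone O at exactly the given geometry."""
    ca = np.zeros(3)
    n = np.array([1.458, 0.0, 0.0])
    u = (ca - n) / np.linalg.norm(ca - n)
    theta = np.radians(angle_deg)
    o = n + distance * (np.cos(theta) * u + np.sin(theta) * np.array([0.0, 1.0, 0.0]))
    donor = make_residue("ALA", 1, [("N", tuple(n)), ("CA", tuple(ca)), ("C", (0.5, 1.4, 0.0))])
    acceptor = make_residue("ALA", 10, [("CA", (o[0] + 3, o[1], o[2])), ("O", tuple(o))])
    return [donor, acceptor]


def test_planted_hbond_geometry_detected():
    bonds = detect_hbonds(_donor_acceptor_pair(2.9, 160.0))
    assert len(bonds) == 1
    (bond,) = bonds
    assert bond.distance == pytest.approx(2.9, abs=1e-6)
    assert bond.angle == pytest.approx(160.0, abs=1e-6)


@pytest.mark.parametrize("distance,angle", [(5.0, 160.0), (2.9, 45.0)])
def test_hbond_criteria_reject_bad_geometry(distance, angle):
    assert detect_hbonds(_donor_acceptor_pair(distance, angle)) == []


def test_hbond_excludes_sequence_neighbor_backbone():
    residues = _donor_acceptor_pair(2.9, 160.0)
    residues[1].number = 2  # make them neighbors
    assert detect_hbonds(residues) == []


def test_hbond_rigid_motion_invariance():
    residues = _donor_acceptor_pair(3.1, 140.0)
    moved = rigid_transform_residues(residues, seed=9)
    a, b = detect_hbonds(residues), detect_hbonds(moved)
    assert len(a) == len(b) == 1
    assert a[0].distance == pytest.approx(b[0].distance, abs=1e-9)
    assert a[0].angle == pytest.approx(b[0].angle, abs=1e-7)


@pytest.mark.parametrize("resname,expected", [
    ("LEU", "nonpolar"), ("GLY", "nonpolar"), ("PRO", "nonpolar"),
    ("SER", "polar"), ("TYR", "polar"),
    ("ASP", "charged"), ("ARG", "charged"), ("HIS", "charged"),
])
def test_polarity_classification(resname, expected):
    assert classify_residue(resname) == expected


def test_unmapped_residue_raises():
    with pytest.raises(KeyError):
        classify_residue("XYZ")


def test_composition_arithmetic():
    residues = [
        make_residue("LEU", 1, [("CA", (0, 0, 0))]),
        make_residue("LEU", 2, [("CA", (5, 0, 0))]),
        make_residue("SER", 3, [("CA", (10, 0, 0))]),
        make_residue("ASP", 4, [("CA", (15, 0, 0))]),
    ]
    stats = composition(residues)
    assert stats.percentages["nonpolar"] == pytest.approx(50.0)
    assert stats.percentages["polar"] == pytest.approx(25.0)
    assert stats.percentages["charged"] == pytest.approx(25.0)


def test_composition_percentages_sum_after_rounding():
    rng = np.random.default_rng(0)
    names = list(RESIDUE_TEMPLATES)
    for _ in range(20):
        residues = [make_residue(rng.choice(names), i + 1, [("CA", (i * 9.0, 0, 0))])
                    for i in range(int(rng.integers(3, 60)))]
        pct = composition(residues).percentages
        rounded = sum(round(v, 1) for v in pct.values())
        assert abs(rounded - 100.0) <= 0.8


def _random_pocket(seed: int, n: int = 30):
    """Scattered single-template residues with real side chains."""
    rng = np.random.default_rng(seed)
    names = list(RESIDUE_TEMPLATES)
    residues = []
    for i in range(n):
        res = _template_residue(str(rng.choice(names)), i + 1, "A", 100 * i)
        shift = rng.uniform(0, 25, size=3)
        for a in res.atoms:
            a.coords = a.coords + shift
        residues.append(res)
    return residues


def test_contact_network_matches_brute_force_on_100_fixtures():
    for seed in range(100):
        residues = _random_pocket(seed)
        got = nonpolar_contact_network(residues, elements=[], cutoff=10.0)
        expected = brute_force_contacts(residues, cutoff=10.0)
        got_map = {(c.residue_a.number, c.residue_b.number): c.distance for c in got.contacts}
        assert set(got_map) == set(expected)
        for pair, d in got_map.items():
            assert d == pytest.approx(expected[pair][0], abs=1e-9)
        assert all(c.kind == "cross-element" for c in got.contacts)  # no elements given


def test_contact_kinds_against_oracle_with_elements():
    residues = _random_pocket(7)
    elements = [
        SSElement(element_id=1, state="H", chain_id="A", residue_numbers=list(range(1, 11))),
        SSElement(element_id=2, state="E", chain_id="A", residue_numbers=list(range(15, 26))),
    ]
    element_of = {n: 1 for n in range(1, 11)}
    element_of.update({n: 2 for n in range(15, 26)})
    got = nonpolar_contact_network(residues, elements, cutoff=10.0)
    expected = brute_force_contacts(residues, cutoff=10.0, element_of=element_of)
    for c in got.contacts:
        assert c.kind == expected[(c.residue_a.number, c.residue_b.number)][1]
    assert got.count("cross-element") + got.count("inside-element") == len(got)


def test_tightening_cutoff_shrinks_contact_set():
    residues = _random_pocket(3)
    wide = nonpolar_contact_network(residues, [], cutoff=12.0)
    narrow = nonpolar_contact_network(residues, [], cutoff=8.0)
    wide_pairs = {(c.residue_a.number, c.residue_b.number) for c in wide.contacts}
    narrow_pairs = {(c.residue_a.number, c.residue_b.number) for c in narrow.contacts}
    assert narrow_pairs <= wide_pairs


def test_contact_beyond_cutoff_excluded():
    a = _template_residue("LEU", 1, "A", 1)
    b = _template_residue("LEU", 5, "A", 50)
    shift = np.array([12.0, 0.0, 0.0]) + (a.sidechain_centroid() - b.sidechain_centroid())
    for atom in b.atoms:
        atom.coords = atom.coords + shift
    assert residue_distance(a, b) == pytest.approx(12.0, abs=1e-9)
    assert len(nonpolar_contact_network([a, b], [], cutoff=10.0)) == 0


def test_contact_network_rigid_motion_invariance():
    residues = _random_pocket(13)
    moved = rigid_transform_residues(residues, seed=21)
    a = nonpolar_contact_network(residues, [], cutoff=10.0)
    b = nonpolar_contact_network(moved, [], cutoff=10.0)
    da = sorted(round(c.distance, 9) for c in a.contacts)
    db = sorted(round(c.distance, 9) for c in b.contacts)
    assert da == db


def test_single_contact_statistics():
    stats = contact_statistics(np.array([7.0]))
    assert stats.n == 1
    assert stats.mean == pytest.approx(7.0)
    assert stats.sd == pytest.approx(0.0)


def test_empty_contact_statistics_flagged():
    stats = contact_statistics(np.array([]))
    assert stats.n == 0 and stats.mean is None and stats.sd is None


def test_population_sd_convention():
    d = np.array([7.0, 8.0, 9.0])
    stats = contact_statistics(d)
    assert stats.sd == pytest.approx(np.sqrt(2.0 / 3.0))  # population, not sample


def test_two_gaussian_mixture_modes_recovered():
    rng = np.random.default_rng(2024)
    component = rng.integers(0, 2, size=1000)
    d = np.where(component == 0, rng.normal(7.7, 0.2, 1000), rng.normal(8.3, 0.2, 1000))
    stats = contact_statistics(d, bin_width=0.25)
    assert len(stats.modes) == 2
    low, high = stats.modes
    assert abs(low - 7.7) <= 0.25
    assert abs(high - 8.3) <= 0.25
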