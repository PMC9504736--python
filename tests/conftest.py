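"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pocketprofiler.structure import Atom, Residue


def make_atom(name: str, coords, element: str | None = None, serial: int = 1,
              occupancy: float = 1.0, record: str = "ATOM") -> Atom:
    return Atom(serial=serial, name=name, element=element or name[0],
                coords=np.asarray(coords, dtype=float), occupancy=occupancy, record=record)


def make_residue(name: str, number: int, atom_spec: list[tuple[str, tuple]],
                 chain_id: str = "A") -> Residue:
    atoms = [make_atom(an, pos, serial=i + 1) for i, (an, pos) in enumerate(atom_spec)]
    return Residue(name=name, number=number, chain_id=chain_id, atoms=atoms)


def rigid_transform_residues(residues: list[Residue], seed: int = 0) -> list[Residue]:
    """A random (seeded) rotation + translation applied to every atom."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-50, 50, size=3)
    out = []
    for res in residues:
        atoms = [Atom(serial=a.serial, name=a.name, element=a.element,
                      coords=rot @ a.coords + shift, occupancy=a.occupancy,
                      record=a.record) for a in res.atoms]
        out.append(Residue(name=res.name, number=res.number,
                           insertion_code=res.insertion_code,
                           chain_id=res.chain_id, atoms=atoms))
    return out


@pytest.fixture
def helix20():
    from pocketprofiler.synthetic import ideal_helix

    return ideal_helix(20)


# ---------------------------------------------------------------------------
# independent oracles

def spherical_cap_pair_area(R: float, d: float) -> float:
    """Accessible area of each of two equal spheres of radius R whose centers
    are d apart (d < 2R): the full sphere minus the buried cap,
    4 pi R^2 - 2 pi R (R - d/2)."""
    return 4.0 * np.pi * R**2 - 2.0 * np.pi * R * (R - d / 2.0)


def brute_force_contacts(residues, cutoff: float, element_of: dict | None = None):
    """Independent O(n^2) enumeration of nonpolar residue contacts by direct
    centroid distances; returns {(num_a, num_b): (distance, kind)}."""
    from pocketprofiler.geometry import POLARITY_CLASSES

    nonpolar = [r for r in residues if POLARITY_CLASSES.get(r.name) == "nonpolar"]
    out = {}
    for i in range(len(nonpolar)):
        for j in range(len(nonpolar)):
            a, b = nonpolar[i], nonpolar[j]
            if a.number >= b.number:
                continue
            if a.chain_id == b.chain_id and abs(a.number - b.number) < 2:
                continue
            d = float(np.linalg.norm(a.sidechain_centroid() - b.sidechain_centroid()))
            if d >= cutoff:
                continue
            ea = element_of.get(a.number) if element_of else None
            eb = element_of.get(b.number) if element_of else None
            kind = "inside-element" if ea is not None and ea == eb else "cross-element"
            out[(a.number, b.number)] = (d, kind)
    return out


def enumerate_alignment_score(a: str, b: str, matrix, gap_open: float = 10.0,
                              gap_extend: float = 0.5) -> float:
    """Optimal global alignment score by exhaustive enumeration of every
    monotone alignment path with affine gap costs (independent of any dynamic
    program); tractable for sequences up to ~length 6."""

    def score(ga: str, gb: str) -> float:
        s = 0.0
        for x, y in zip(ga, gb):
            if x != "-" and y != "-":
                s += matrix[x, y]
        for g in (ga, gb):
            run = 0
            for ch in g:
                if ch == "-":
                    run += 1
                else:
                    if run:
                        s -= gap_open + gap_extend * (run - 1)
                    run = 0
            if run:
                s -= gap_open + gap_extend * (run - 1)
        return s

    best = -np.inf

    def recurse(i: int, j: int, ga: list, gb: list):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score("".join(ga), "".join(gb)))
            return
        if i < len(a) and j < len(b):
            ga.append(a[i]); gb.append(b[j])
            recurse(i + 1, j + 1, ga, gb)
            ga.pop(); gb.pop()
        if i < len(a):
            ga.append(a[i]); gb.append("-")
            recurse(i + 1, j, ga, gb)
            ga.pop(); gb.pop()
        if j < len(b):
            ga.append("-"); gb.append(b[j])
            recurse(i, j + 1, ga, gb)
            ga.pop(); gb.pop()

    recurse(0, 0, [], [])
    return float(best)


def group_elements_oracle(state_string: str, min_len_H: int = 4, min_len_E: int = 2):
    """Run-length oracle for element grouping (itertools-based, independent of
    the implementation's scanner)."""
    import itertools

    out = []
    pos = 0
    for state, group in itertools.groupby(state_string):
        run = len(list(group))
        if state == "H" and run >= min_len_H or state == "E" and run >= min_len_E:
            out.append((state, pos, run))
        pos += run
    return out
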