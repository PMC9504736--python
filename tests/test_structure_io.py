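"""PDB parsing, pocket selection, ligand extraction and round-tripping."""

import numpy as np
import pytest

from pocketprofiler.structure import (
    PDBParseError,
    extract_ligand,
    molecular_weight,
    parse_pdb,
    select_pocket,
    strip_non_structural,
    write_pdb,
)
from pocketprofiler.synthetic import ideal_helix, residues_to_model

MINIMAL_ATOM = (
    "ATOM      1  CA  GLY A  42      11.104  13.207   2.100  1.00 20.00           C\n"
)


def hetatm_line(serial: int, name: str, res: str, num: int, x: float, element: str) -> str:
    return (f"HETATM{serial:>5}  {name:<3} {res:>3} A{num:>4}    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}")


def test_single_atom_record():
    model = parse_pdb(MINIMAL_ATOM)
    assert list(model.chains) == ["A"]
    (res,) = model.chains["A"]
    assert (res.name, res.number) == ("GLY", 42)
    assert res.atoms[0].name == "CA"
    np.testing.assert_allclose(res.atoms[0].coords, [11.104, 13.207, 2.100])


@pytest.mark.parametrize("bad", ["", "HEADER only text\nEND\n"])
def test_no_coordinate_records_is_an_error(bad):
    with pytest.raises(PDBParseError):
        parse_pdb(bad)


def test_malformed_record_names_line_number():
    text = MINIMAL_ATOM + "ATOM      2  CA  GLY A  43      xx.xxx  13.207   2.100\n"
    with pytest.raises(PDBParseError, match="line 2"):
        parse_pdb(text)


def test_helix_roundtrip_preserves_numbering_and_coords(helix20):
    model = residues_to_model(helix20)
    reparsed = parse_pdb(write_pdb(model))
    assert [r.number for r in reparsed.chains["A"]] == [r.number for r in helix20]
    for orig, back in zip(helix20, reparsed.chains["A"]):
        assert orig.name == back.name
        np.testing.assert_allclose(
            np.array([a.coords for a in back.atoms]),
            np.array([a.coords for a in orig.atoms]),
            atol=5e-4,  # PDB stores 3 decimals
        )


def test_roundtrip_is_stable_after_first_write(helix20):
    model = residues_to_model(helix20)
    once = write_pdb(model)
    assert write_pdb(parse_pdb(once)) == once


def test_altloc_keeps_highest_occupancy_then_alphabetical():
    text = (
        "ATOM      1  CA BGLY A   1       1.000   0.000   0.000  0.70 20.00           C\n"
        "ATOM      2  CA AGLY A   1       2.000   0.000   0.000  0.30 20.00           C\n"
        "ATOM      3  CB BGLY A   1       3.000   0.000   0.000  0.50 20.00           C\n"
        "ATOM      4  CB AGLY A   1       4.000   0.000   0.000  0.50 20.00           C\n"
    )
    (res,) = parse_pdb(text).chains["A"]
    assert len(res.atoms) == 2
    assert res.atom("CA").coords[0] == 1.0  # occupancy 0.70 wins
    assert res.atom("CB").coords[0] == 4.0  # tie -> altloc A


def test_strip_removes_waters_and_is_idempotent():
    lines = [MINIMAL_ATOM.rstrip("\n")]
    for i in range(50):
        lines.append(hetatm_line(100 + i, "O", "HOH", 200 + i, float(i), "O"))
    lines.append(hetatm_line(999, "C1", "LIG", 900, 5.0, "C"))
    model = parse_pdb("\n".join(lines) + "\n")
    assert len(model.hetero_groups) == 51
    stripped = strip_non_structural(model, {"HOH"})
    assert stripped.hetcodes() == ["LIG"]
    again = strip_non_structural(stripped, {"HOH"})
    assert again.hetero_groups == stripped.hetero_groups
    untouched = strip_non_structural(model, set())
    assert len(untouched.hetero_groups) == 51


def test_select_pocket_range_counts_and_errors(helix20):
    model = residues_to_model(helix20)
    pocket = select_pocket(model, "A", 5, 12)
    assert len(pocket) == 8
    assert pocket.missing_numbers == []
    single = select_pocket(model, "A", 7, 7)
    assert len(single) == 1 and single.residues[0].number == 7
    with pytest.raises(KeyError):
        select_pocket(model, "Z", 1, 5)
    with pytest.raises(ValueError):
        select_pocket(model, "A", 100, 120)


def test_select_pocket_records_missing_numbers(helix20):
    model = residues_to_model([r for r in helix20 if r.number != 10])
    pocket = select_pocket(model, "A", 5, 15)
    assert len(pocket) == 10
    assert pocket.missing_numbers == [10]
    # count <= span, equality iff nothing missing
    assert len(pocket) <= pocket.end_number - pocket.start_number + 1


def test_extract_ligand_and_molecular_weight():
    lines = [MINIMAL_ATOM.rstrip("\n")]
    for i, el in enumerate(["C", "C", "C", "N", "N"]):
        lines.append(hetatm_line(10 + i, f"{el}{i+1}", "LIG", 900, float(i), el))
    model = parse_pdb("\n".join(lines) + "\n")
    lig = extract_ligand(model, "LIG")
    assert len(lig.atoms) == 5
    # 3 C + 2 N, independent hand sum of standard atomic weights
    assert molecular_weight(lig) == pytest.approx(3 * 12.011 + 2 * 14.007, abs=0.02)
    with pytest.raises(KeyError, match="LIG"):
        extract_ligand(model, "HOH")


def test_extract_ligand_error_after_strip():
    text = MINIMAL_ATOM + hetatm_line(10, "O", "HOH", 500, 1.0, "O") + "\n"
    model = strip_non_structural(parse_pdb(text), {"HOH"})
    with pytest.raises(KeyError):
        extract_ligand(model, "HOH")
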