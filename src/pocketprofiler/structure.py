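"""Atomic structure model and PDB input/output.

The in-memory model is deliberately small: atoms, residues, polymer chains
and hetero groups, all keyed by the author-assigned PDB numbering so that
residues can be addressed the way the structural literature addresses them
(ARG879, LEU983, ...).  Parsing is delegated to gemmi; on top of it this
module validates fixed-column records, collapses alternate conformations to
the highest-occupancy one, and keeps only the first MODEL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "PocketModel",
    "LigandMolecule",
    "PDBParseError",
    "parse_pdb",
    "read_pdb",
    "write_pdb",
    "strip_non_structural",
    "select_pocket",
    "extract_ligand",
    "molecular_weight",
]

#: heteroatom codes removed by default: water plus common buffer/cryo agents
DEFAULT_STRIP = frozenset(
    {"HOH", "DOD", "SO4", "PO4", "GOL", "EDO", "PEG", "ACT", "DMS", "CL", "NA", "MG"}
)

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input; carries the offending line number."""


@dataclass(eq=False)
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) in Angstrom
    altloc: str = ""
    occupancy: float = 1.0
    record: str = "ATOM"  # ATOM | HETATM

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass(eq=False)
class Residue:
    name: str
    number: int
    insertion_code: str = ""
    chain_id: str = "A"
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.name}{self.number}{self.insertion_code}".strip()

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.heavy_atoms()], dtype=float)

    def sidechain_centroid(self) -> np.ndarray:
        """Centroid of side-chain heavy atoms; falls back to CA (e.g. glycine)."""
        side = [a for a in self.heavy_atoms() if a.name not in BACKBONE_NAMES]
        if side:
            return np.mean([a.coords for a in side], axis=0)
        ca = self.atom("CA")
        if ca is not None:
            return np.asarray(ca.coords, dtype=float)
        return np.mean(self.heavy_coords(), axis=0)


@dataclass(eq=False)
class StructureModel:
    """Polymer chains plus hetero groups, in file order."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    hetero_groups: dict[tuple[str, str, int], list[Atom]] = field(default_factory=dict)
    source_id: str = ""

    def first_chain_id(self) -> str:
        if not self.chains:
            raise ValueError("structure has no polymer chains")
        return next(iter(self.chains))

    def all_polymer_atoms(self) -> list[Atom]:
        return [a for residues in self.chains.values() for r in residues for a in r.atoms]

    def hetcodes(self) -> list[str]:
        seen: list[str] = []
        for code, _, _ in self.hetero_groups:
            if code not in seen:
                seen.append(code)
        return seen


@dataclass(eq=False)
class PocketModel:
    """Contiguous author-numbered fragment of one chain (the binding-pocket niche)."""

    parent: StructureModel
    chain_id: str
    start_number: int
    end_number: int
    residues: list[Residue]
    missing_numbers: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def heavy_atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.heavy_atoms()]


@dataclass(eq=False)
class LigandMolecule:
    hetcode: str
    atoms: list[Atom]
    name: str = ""

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.heavy_atoms()], dtype=float)


# ---------------------------------------------------------------------------
# parsing

_WATER = {"HOH", "DOD", "WAT"}


def _validate_fixed_columns(text: str) -> None:
    n_coord_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM", "ATOM ")):
            if len(line) < 54:
                raise PDBParseError(f"line {lineno}: coordinate record shorter than 54 columns")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: malformed fixed-column field ({exc})") from exc
            n_coord_records += 1
    if n_coord_records == 0:
        raise PDBParseError("input contains no ATOM or HETATM records")


def _pick_altloc(atoms: list[Atom]) -> list[Atom]:
    """Collapse alternate locations: per atom name keep the highest-occupancy
    conformer, ties broken by the alphabetically first altloc identifier."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept: list[Atom] = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc))
        kept.append(replace(best, altloc="", coords=np.array(best.coords, dtype=float)))
    return kept


def _element_of(gatom: gemmi.Atom) -> str:
    el = gatom.element.name.strip()
    if el and el != "X":
        return el.upper() if len(el) == 1 else el[0].upper() + el[1:].lower()
    # fall back to the atom-name convention: first alphabetic character
    for ch in gatom.name:
        if ch.isalpha():
            return ch.upper()
    raise PDBParseError(f"cannot infer element for atom {gatom.name!r}")


def parse_pdb(text: str, source_id: str = "") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only the first MODEL is used; alternate conformations are collapsed to the
    highest-occupancy one.  Raises :class:`PDBParseError` (with a line number)
    on malformed fixed-column records or input without coordinate records.
    """
    _validate_fixed_columns(text)
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    model = StructureModel(source_id=source_id or st.name)
    gmodel = st[0]
    for gchain in gmodel:
        cid = gchain.name or "A"
        for gres in gchain:
            atoms = []
            for ga in gres:
                atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=ga.name,
                        element=_element_of(ga),
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z], dtype=float),
                        altloc=(ga.altloc or "").strip("\x00"),
                        occupancy=float(ga.occ),
                        record="HETATM" if gres.het_flag == "H" else "ATOM",
                    )
                )
            atoms = _pick_altloc(atoms)
            is_het = gres.het_flag == "H" or gres.name in _WATER
            if is_het:
                model.hetero_groups[(gres.name, cid, gres.seqid.num)] = atoms
            else:
                res = Residue(
                    name=gres.name,
                    number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    chain_id=cid,
                    atoms=atoms,
                )
                model.chains.setdefault(cid, []).append(res)
    return model


def read_pdb(path, source_id: str = "") -> StructureModel:
    with open(path) as fh:
        return parse_pdb(fh.read(), source_id=source_id or str(path))


# ---------------------------------------------------------------------------
# writing (fixtures and stripped models round-trip through the normal reader)

def _format_atom_line(record: str, serial: int, atom: Atom, resname: str,
                      chain_id: str, resnum: int, icode: str) -> str:
    name = atom.name
    # PDB convention: 1-2 char element symbols start in column 13, shorter
    # atom names are left-padded with one space
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    x, y, z = atom.coords
    return (
        f"{record:<6}{serial:>5} {name:<4}{'':1}{resname:>3} {chain_id:1}"
        f"{resnum:>4}{icode:1}   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2}"
    )


def write_pdb(model: StructureModel) -> str:
    lines: list[str] = []
    serial = 0
    for cid, residues in model.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                lines.append(
                    _format_atom_line("ATOM", serial, atom, res.name, cid,
                                      res.number, res.insertion_code or " ")
                )
        serial += 1
        lines.append(f"TER   {serial:>5}")
    for (code, cid, num), atoms in model.hetero_groups.items():
        for atom in atoms:
            serial += 1
            lines.append(_format_atom_line("HETATM", serial, atom, code, cid, num, " "))
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# selection operations

def strip_non_structural(model: StructureModel, remove: frozenset[str] | set[str] | None = None) -> StructureModel:
    """Return a copy without hetero groups whose code is in ``remove``
    (default: water plus common buffer components).  Idempotent; the polymer
    is untouched and removing an absent code is a no-op."""
    if remove is None:
        remove = DEFAULT_STRIP
    kept = {k: v for k, v in model.hetero_groups.items() if k[0] not in remove}
    return StructureModel(chains=model.chains, hetero_groups=kept, source_id=model.source_id)


def select_pocket(model: StructureModel, chain_id: str | None, start: int, end: int) -> PocketModel:
    """Residues with author numbers in [start, end] of one chain.

    Numbers absent from the deposited model are recorded in
    ``missing_numbers`` rather than silently dropped.
    """
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    cid = chain_id if chain_id is not None else model.first_chain_id()
    if cid not in model.chains:
        raise KeyError(f"chain {cid!r} not in structure (have {sorted(model.chains)})")
    residues = [r for r in model.chains[cid] if start <= r.number <= end]
    if not residues:
        raise ValueError(f"no residues of chain {cid} in range {start}-{end}")
    present = {r.number for r in residues}
    missing = [n for n in range(start, end + 1) if n not in present]
    return PocketModel(
        parent=model, chain_id=cid, start_number=start, end_number=end,
        residues=residues, missing_numbers=missing,
    )


def extract_ligand(model: StructureModel, hetcode: str) -> LigandMolecule:
    """Pull one hetero component out as a ligand (heavy atoms only).

    When several copies of the component are present, the copy with the most
    atoms is used (ties: first in file order).
    """
    copies = [(key, atoms) for key, atoms in model.hetero_groups.items() if key[0] == hetcode]
    if not copies:
        raise KeyError(
            f"hetero component {hetcode!r} not present; available: {model.hetcodes()}"
        )
    key, atoms = max(copies, key=lambda kv: len(kv[1]))
    heavy = [a for a in atoms if not a.is_hydrogen]
    if not heavy:
        raise ValueError(f"component {hetcode!r} has no heavy atoms")
    return LigandMolecule(hetcode=hetcode, atoms=heavy, name=f"{hetcode} {key[1]}{key[2]}")


def molecular_weight(ligand: LigandMolecule) -> float:
    """Sum of atomic weights of the ligand's atoms, in Da (hydrogens included
    if present in the record)."""
    return float(sum(gemmi.Element(a.element).weight for a in ligand.atoms))
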