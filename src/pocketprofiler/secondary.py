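"""Three-state secondary structure (H/E/C) from backbone geometry.

Assignment follows the Kabsch–Sander hydrogen-bond pattern method: backbone
N-H...O=C bonds are scored with the electrostatic energy

    E = 0.084 * 332 * (1/d_ON + 1/d_CH - 1/d_OH - 1/d_CN)   [kcal/mol]

and count as bonds below a cutoff (default -0.5 kcal/mol).  Amide hydrogens,
absent from X-ray models, are reconstructed on the nitrogen along the
direction of the preceding residue's C=O bond (N-H length 1.01 A).  Runs of
i -> i+4 bonds become helix, bridge ladders become strand, everything else is
coil.  An external DSSP or STRIDE assignment can be loaded instead for exact
reproduction of published element counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure import PocketModel, Residue

__all__ = [
    "SSEAnnotation",
    "SSElement",
    "assign_sse",
    "group_elements",
    "load_external_sse",
    "apply_external",
]

KS_COUPLING = 0.084 * 332.0  # partial charges times electrostatic constant
DEFAULT_ENERGY_CUTOFF = -0.5  # kcal/mol
NH_LENGTH = 1.01  # A, reconstructed amide hydrogen
PEPTIDE_BOND_MAX = 2.5  # A, C(i)-N(i+1) distance beyond which the chain is broken

ResidueKey = tuple[str, int, str]


@dataclass
class SSEAnnotation:
    """Per-residue three-state assignment in residue order."""

    keys: list[ResidueKey]
    states: dict[ResidueKey, str]

    def __post_init__(self) -> None:
        bad = {s for s in self.states.values()} - {"H", "E", "C"}
        if bad:
            raise ValueError(f"invalid states {bad}; only H/E/C allowed")

    def string(self) -> str:
        return "".join(self.states[k] for k in self.keys)

    def __len__(self) -> int:
        return len(self.keys)

    @classmethod
    def from_string(cls, s: str, chain_id: str = "A", start: int = 1) -> "SSEAnnotation":
        keys = [(chain_id, start + i, "") for i in range(len(s))]
        return cls(keys=keys, states={k: c for k, c in zip(keys, s)})


@dataclass
class SSElement:
    element_id: int
    state: str  # H | E
    chain_id: str
    residue_numbers: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.residue_numbers)

    def __contains__(self, number: int) -> bool:
        return number in self.residue_numbers


def _backbone(residues: list[Residue]):
    """Backbone coordinate arrays and validity mask; NaN where atoms are absent."""
    n = len(residues)
    coords = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O")}
    for i, res in enumerate(residues):
        for name in coords:
            a = res.atom(name)
            if a is not None:
                coords[name][i] = a.coords
    complete = ~np.any(
        [np.isnan(coords[name]).any(axis=1) for name in coords], axis=0
    )
    return coords, complete


def _chain_breaks(residues: list[Residue], coords, complete) -> np.ndarray:
    """broken[i] is True when no peptide bond connects residue i to i+1."""
    n = len(residues)
    broken = np.zeros(max(n - 1, 0), dtype=bool)
    for i in range(n - 1):
        if residues[i].chain_id != residues[i + 1].chain_id:
            broken[i] = True
            continue
        if not (complete[i] and complete[i + 1]):
            broken[i] = True
            continue
        d = np.linalg.norm(coords["C"][i] - coords["N"][i + 1])
        broken[i] = d > PEPTIDE_BOND_MAX
    return broken


def _ks_hbond_matrix(residues, coords, complete, broken, cutoff: float) -> np.ndarray:
    """hb[i, j] is True when C=O of residue i accepts the amide H-N of residue j."""
    n = len(residues)
    hb = np.zeros((n, n), dtype=bool)
    # reconstructed amide H for each donor (needs a preceding bonded residue, not PRO)
    h_pos = np.full((n, 3), np.nan)
    for j in range(1, n):
        if broken[j - 1] or not complete[j] or not complete[j - 1]:
            continue
        if residues[j].name == "PRO":
            continue
        co = coords["C"][j - 1] - coords["O"][j - 1]
        norm = np.linalg.norm(co)
        if norm < 1e-9:
            continue
        h_pos[j] = coords["N"][j] + NH_LENGTH * co / norm

    donors = [j for j in range(n) if not np.isnan(h_pos[j]).any()]
    for i in range(n):  # acceptor C=O
        if not complete[i]:
            continue
        c, o = coords["C"][i], coords["O"][i]
        for j in donors:
            if abs(i - j) < 2:
                continue
            nn, h = coords["N"][j], h_pos[j]
            d_on = np.linalg.norm(o - nn)
            if d_on > 7.0:  # energy is negligible beyond this
                continue
            d_ch = np.linalg.norm(c - h)
            d_oh = np.linalg.norm(o - h)
            d_cn = np.linalg.norm(c - nn)
            if min(d_on, d_ch, d_oh, d_cn) < 0.5:
                energy = -9.9  # clashing atoms: saturated minimum
            else:
                energy = KS_COUPLING * (1 / d_on + 1 / d_ch - 1 / d_oh - 1 / d_cn)
            if energy < cutoff:
                hb[i, j] = True
    return hb


def _contiguous(broken: np.ndarray, i: int, j: int) -> bool:
    """True when residues i..j (i<=j) form one unbroken stretch."""
    return not broken[i:j].any()


def assign_sse(pocket: PocketModel | list[Residue], energy_cutoff: float = DEFAULT_ENERGY_CUTOFF) -> SSEAnnotation:
    """Kabsch-Sander style H/E/C assignment for a pocket or residue list.

    Residues without a complete backbone are coil; pockets shorter than five
    residues are entirely coil (no H-bond pattern fits).
    """
    residues = pocket.residues if isinstance(pocket, PocketModel) else list(pocket)
    keys = [r.key for r in residues]
    n = len(residues)
    states = {k: "C" for k in keys}
    if n < 5:
        return SSEAnnotation(keys=keys, states=states)

    coords, complete = _backbone(residues)
    broken = _chain_breaks(residues, coords, complete)
    hb = _ks_hbond_matrix(residues, coords, complete, broken, energy_cutoff)

    # 4-turns: C=O(i) ... H-N(i+4) over an unbroken stretch
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if hb[i, i + 4] and _contiguous(broken, i, i + 4):
            turn4[i] = True

    is_h = np.zeros(n, dtype=bool)
    for i in range(1, n - 3):
        if turn4[i - 1] and turn4[i]:
            is_h[i : i + 4] = True

    # bridges (parallel or antiparallel) between non-overlapping stretches
    is_e = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para or anti:
                is_e[i] = is_e[j] = True

    for i, k in enumerate(keys):
        if is_h[i]:
            states[k] = "H"
        elif is_e[i]:
            states[k] = "E"
    return SSEAnnotation(keys=keys, states=states)


def group_elements(annotation: SSEAnnotation, min_len_H: int = 4, min_len_E: int = 2) -> list[SSElement]:
    """Maximal runs of H / E become numbered elements; runs shorter than the
    state's minimum length are treated as coil.  Runs are broken at chain
    changes and numbering gaps."""
    elements: list[SSElement] = []
    run_keys: list[ResidueKey] = []
    run_state = "C"

    def flush():
        nonlocal run_keys
        if run_state == "H" and len(run_keys) >= min_len_H or run_state == "E" and len(run_keys) >= min_len_E:
            elements.append(
                SSElement(
                    element_id=len(elements) + 1,
                    state=run_state,
                    chain_id=run_keys[0][0],
                    residue_numbers=[k[1] for k in run_keys],
                )
            )
        run_keys = []

    prev_key: ResidueKey | None = None
    for key in annotation.keys:
        state = annotation.states[key]
        discontinuous = prev_key is not None and (
            key[0] != prev_key[0] or key[1] > prev_key[1] + 1
        )
        if state != run_state or discontinuous:
            flush()
            run_state = state
        if state in ("H", "E"):
            run_keys.append(key)
        prev_key = key
    flush()
    return elements


# ---------------------------------------------------------------------------
# external assignments (DSSP / STRIDE output files)

_EXTERNAL_MAP = {"G": "H", "H": "H", "I": "H", "E": "E", "B": "E", "b": "E"}


def _parse_stride(lines: list[str]):
    out = []
    for line in lines:
        if not line.startswith("ASG"):
            continue
        parts = line.split()
        # ASG  resname chain resnum ordinal state ...
        name, chain, resnum, state = parts[1], parts[2], parts[3], parts[5]
        icode = ""
        if resnum[-1].isalpha():
            resnum, icode = resnum[:-1], resnum[-1]
        out.append(((chain, int(resnum), icode), state))
    return out


def _parse_dssp(lines: list[str]):
    out = []
    in_table = False
    for line in lines:
        if line.startswith("  #  RESIDUE"):
            in_table = True
            continue
        if not in_table or len(line) < 17:
            continue
        if line[13] == "!":  # chain break marker
            continue
        try:
            resnum = int(line[5:10])
        except ValueError:
            continue
        icode = line[10].strip()
        chain = line[11].strip() or "A"
        state = line[16]
        out.append(((chain, resnum, icode), state))
    return out


def load_external_sse(text: str) -> SSEAnnotation:
    """Read a STRIDE (ASG records) or DSSP (columnar) output file and collapse
    the eight-state alphabet to H/E/C (G,I -> H; B -> E)."""
    lines = text.splitlines()
    records = _parse_stride(lines)
    if not records:
        records = _parse_dssp(lines)
    if not records:
        raise ValueError("no secondary-structure records found in external file")
    keys = [k for k, _ in records]
    states = {k: _EXTERNAL_MAP.get(s, "C") for k, s in records}
    return SSEAnnotation(keys=keys, states=states)


def apply_external(pocket: PocketModel, external: SSEAnnotation) -> SSEAnnotation:
    """Restrict an external annotation to a pocket; pocket residues missing
    from the file are coil and reported with a warning."""
    keys = [r.key for r in pocket.residues]
    unmatched = [k for k in keys if k not in external.states]
    if unmatched:
        warnings.warn(f"{len(unmatched)} pocket residues missing from external assignment: {unmatched[:5]}...")
    states = {k: external.states.get(k, "C") for k in keys}
    return SSEAnnotation(keys=keys, states=states)
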