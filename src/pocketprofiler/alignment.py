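"""Global pairwise alignment of pocket sequences with Clustal-style
conservation annotation.

Two pocket sequences are aligned by Needleman-Wunsch with BLOSUM62 and affine
gaps (open 10, extend 0.5), the standard two-sequence equivalent of a Clustal
run.  The conservation line marks identities (*), substitutions within a
Clustal "strong" group (:) and within a "weak" group (.); percent identity
defaults to identical columns over the shorter sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .structure import PocketModel

__all__ = [
    "PocketSequence",
    "AlignmentResult",
    "THREE_TO_ONE",
    "CLUSTAL_STRONG_GROUPS",
    "CLUSTAL_WEAK_GROUPS",
    "pocket_sequence",
    "needleman_wunsch",
    "conservation_line",
    "identity_percent",
    "write_clustal",
    "write_fasta",
    "read_fasta",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues fold back onto their parents
    "MSE": "M", "SEC": "U", "PYL": "O",
}

# canonical Clustal conservation groups
CLUSTAL_STRONG_GROUPS = [
    set("STA"), set("NEQK"), set("NHQK"), set("NDEQ"), set("QHRK"),
    set("MILV"), set("MILF"), set("HY"), set("FYW"),
]
CLUSTAL_WEAK_GROUPS = [
    set("CSA"), set("ATV"), set("SAG"), set("STNK"), set("STPA"),
    set("SGND"), set("SNDEQK"), set("NDEQHK"), set("NEQHRK"),
    set("FVLIM"), set("HFY"),
]


@dataclass
class PocketSequence:
    sequence: str
    source: str = ""
    numbering_offset: int = 1  # author number of the first residue

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    conservation: str
    identity_percent: float
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


def pocket_sequence(pocket: PocketModel) -> PocketSequence:
    """One-letter sequence of a pocket; unknown residues map to X (missing
    residue numbers are simply absent, as in the deposited coordinates)."""
    letters = [THREE_TO_ONE.get(r.name, "X") for r in pocket.residues]
    return PocketSequence(
        sequence="".join(letters),
        source=f"{pocket.parent.source_id}:{pocket.chain_id}"
               f"/{pocket.start_number}-{pocket.end_number}",
        numbering_offset=pocket.residues[0].number,
    )


def _aligner(matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def needleman_wunsch(
    a: PocketSequence | str,
    b: PocketSequence | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    denominator_mode: str = "shorter_sequence_length",
) -> AlignmentResult:
    """Optimal global alignment under affine gap penalties.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; terminal gaps
    are penalized like internal ones.  The traceback is deterministic (the
    highest-priority optimal alignment of the aligner is reported).
    """
    seq_a = a.sequence if isinstance(a, PocketSequence) else a
    seq_b = b.sequence if isinstance(b, PocketSequence) else b
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(seq_a, seq_b)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    result = AlignmentResult(
        aligned_a=ga,
        aligned_b=gb,
        conservation="",
        identity_percent=0.0,
        score=float(alignment.score),
    )
    result.conservation = conservation_line(result)
    result.identity_percent = identity_percent(result, denominator_mode)
    return result


def conservation_line(alignment: AlignmentResult) -> str:
    """Clustal notation per column: '*' identity, ':' strong-group
    substitution, '.' weak-group substitution, space otherwise or at gaps."""
    out = []
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x == "-" or y == "-":
            out.append(" ")
        elif x == y:
            out.append("*")
        elif any(x in g and y in g for g in CLUSTAL_STRONG_GROUPS):
            out.append(":")
        elif any(x in g and y in g for g in CLUSTAL_WEAK_GROUPS):
            out.append(".")
        else:
            out.append(" ")
    return "".join(out)


def identity_percent(alignment: AlignmentResult, denominator_mode: str = "shorter_sequence_length") -> float:
    """100 x identical columns / denominator."""
    identical = sum(
        1 for x, y in zip(alignment.aligned_a, alignment.aligned_b) if x == y and x != "-"
    )
    if denominator_mode == "alignment_length":
        denom = len(alignment.aligned_a)
    elif denominator_mode == "shorter_sequence_length":
        denom = min(
            len(alignment.aligned_a.replace("-", "")),
            len(alignment.aligned_b.replace("-", "")),
        )
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    return 100.0 * identical / denom


def write_clustal(alignment: AlignmentResult, name_a: str = "seqA", name_b: str = "seqB",
                  width: int = 60) -> str:
    """Clustal-style ALN text: 60-column blocks with the conservation line."""
    label = max(len(name_a), len(name_b)) + 4
    lines = ["CLUSTAL-style pairwise alignment", ""]
    for start in range(0, len(alignment.aligned_a), width):
        sl = slice(start, start + width)
        lines.append(f"{name_a:<{label}}{alignment.aligned_a[sl]}")
        lines.append(f"{name_b:<{label}}{alignment.aligned_b[sl]}")
        lines.append(f"{'':<{label}}{alignment.conservation[sl]}")
        lines.append("")
    return "\n".join(lines)


def write_fasta(records: list[tuple[str, str]]) -> str:
    out = []
    for name, seq in records:
        out.append(f">{name}")
        out.extend(seq[i:i + 60] for i in range(0, len(seq), 60))
    return "\n".join(out) + "\n"


def read_fasta(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, list[str]]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            records.append((line[1:].strip(), []))
        elif records:
            records[-1][1].append(line)
    return [(name, "".join(parts)) for name, parts in records]
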