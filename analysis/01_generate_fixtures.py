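#!/usr/bin/env python
"""Generate the synthetic fixture structures used by the downstream analyses.

Writes, under results/fixtures/:
  helix20.pdb        - ideal 20-residue alpha-helix backbone
  strand_pair.pdb    - antiparallel beta-strand pair at 4.8 A separation
  mixed_pocket.pdb   - 40-residue pocket with 2 helices + 2 paired strands
  toy_complex.pdb    - 10-residue pocket with a ligand, 4 planted hydrophobic
                       contacts and 1 planted hydrogen bond
"""

from pathlib import Path

from pocketprofiler.structure import write_pdb
from pocketprofiler.synthetic import (
    LigandPlan,
    PlantedHBond,
    SyntheticSpec,
    ideal_helix,
    ideal_strand_pair,
    residues_to_model,
    toy_complex,
)

OUT = Path("results/fixtures")
OUT.mkdir(parents=True, exist_ok=True)

(OUT / "helix20.pdb").write_text(write_pdb(residues_to_model(ideal_helix(20))))
(OUT / "strand_pair.pdb").write_text(write_pdb(residues_to_model(ideal_strand_pair(8))))

mixed = SyntheticSpec(
    n_residues=40,
    element_plan=[("H", 10), ("C", 3), ("E", 6), ("C", 3), ("E", 6), ("C", 2), ("H", 10)],
)
(OUT / "mixed_pocket.pdb").write_text(write_pdb(toy_complex(mixed)))

complex_spec = SyntheticSpec(
    n_residues=10,
    residue_names=["LEU", "VAL", "ALA", "GLY", "CYS", "SER", "ASP", "ARG", "ASN", "LEU"],
    ligand_plan=LigandPlan(n_atoms=5, elements=["C"] * 5,
                           near=[(0, 6.0), (1, 7.0), (2, 8.0), (3, 9.5)]),
    planted_hbonds=[PlantedHBond(residue_index=4, protein_atom="O",
                                 ligand_is_donor=True, distance=2.9, angle=170.0)],
    seed=42,
)
(OUT / "toy_complex.pdb").write_text(write_pdb(toy_complex(complex_spec)))

print(f"wrote 4 fixtures to {OUT}/")
print("planted ground truth of toy_complex.pdb: 4 hydrophobic contacts "
      "(6.0/7.0/8.0/9.5 A), 1 hydrogen bond (2.9 A, 170 deg) at residue 5")
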