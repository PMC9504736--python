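{
  "description": "Published reference values for the JAK1 (PDB 6N7A, chain range 865-1154) and JAK2 (PDB 4YTH, 842-1130) ligand-binding pockets. Affinity energies are context only (docking is out of scope) and carry no tolerance, so compare_report never scores them.",
  "pockets": {
    "JAK1": {
      "pdb_id": "6N7A",
      "range": "865:1154",
      "n_residues": {"value": 290, "tol": 0, "kind": "abs"},
      "first_residue": {"value": "VAL"},
      "last_residue": {"value": "LYS"},
      "sasa_total": {"value": 29255.336, "tol": 0.05, "kind": "rel"},
      "n_hbonds": {"value": 189, "tol": 0.10, "kind": "rel"},
      "pct_nonpolar": {"value": 36.8, "tol": 0.5, "kind": "abs"},
      "pct_polar": {"value": 30.9, "tol": 0.5, "kind": "abs"},
      "pct_charged": {"value": 31.6, "tol": 0.5, "kind": "abs"},
      "n_cross_element": {"value": 310, "tol": 0.15, "kind": "rel"},
      "n_inside_element": {"value": 43, "tol": 0.15, "kind": "rel"},
      "cross_mean": {"value": 8.28, "tol": 0.3, "kind": "abs"},
      "cross_sd": {"value": 1.37},
      "inside_mean": {"value": 7.80},
      "inside_sd": {"value": 1.54},
      "n_helices": {"value": 17},
      "n_strands": {"value": 13}
    },
    "JAK2": {
      "pdb_id": "4YTH",
      "range": "842:1130",
      "n_residues": {"value": 289, "tol": 0, "kind": "abs"},
      "first_residue": {"value": "THR"},
      "last_residue": {"value": "MET"},
      "sasa_total": {"value": 31252.359, "tol": 0.05, "kind": "rel"},
      "n_hbonds": {"value": 198, "tol": 0.10, "kind": "rel"},
      "pct_nonpolar": {"value": 38.4, "tol": 0.5, "kind": "abs"},
      "pct_polar": {"value": 30.4, "tol": 0.5, "kind": "abs"},
      "pct_charged": {"value": 30.4, "tol": 0.5, "kind": "abs"},
      "n_cross_element": {"value": 333, "tol": 0.15, "kind": "rel"},
      "n_inside_element": {"value": 38, "tol": 0.15, "kind": "rel"},
      "cross_mean": {"value": 8.25, "tol": 0.3, "kind": "abs"},
      "cross_sd": {"value": 1.40},
      "inside_mean": {"value": 7.67},
      "inside_sd": {"value": 1.62},
      "n_helices": {"value": 17},
      "n_strands": {"value": 12}
    }
  },
  "contact_distance_modes": {
    "lower": {"value": 7.75, "tol": 0.25, "kind": "abs"},
    "upper": {"value": 8.3, "tol": 0.25, "kind": "abs"}
  },
  "alignment": {
    "identity_percent": {"value": 54.0, "tol": 3.0, "kind": "abs"}
  },
  "ligand_profiles": [
    {"ligand": "decernotinib", "pocket": "JAK1",
     "locus": ["ARG879", "LEU881", "GLY884", "GLY962"],
     "n_hb": {"value": 1}, "n_hydrophobic": {"value": 10},
     "affinity_kcal_mol": -8.7, "context_only": ["affinity_kcal_mol"]},
    {"ligand": "KEV", "pocket": "JAK1",
     "locus": ["ARG879", "LEU881", "GLY884", "GLY962"],
     "n_hb": {"value": 1}, "n_hydrophobic": {"value": 15},
     "affinity_kcal_mol": -8.7, "context_only": ["affinity_kcal_mol"]},
    {"ligand": "ruxolitinib", "pocket": "JAK1",
     "locus": ["ARG879", "LEU881", "GLY884", "GLY962"],
     "n_hb": {"value": 0, "tol": 0, "kind": "abs"}, "n_hydrophobic": {"value": 16},
     "n_hydrophobic_alternative": 18,
     "affinity_kcal_mol": -8.3, "context_only": ["affinity_kcal_mol"]},
    {"ligand": "decernotinib", "pocket": "JAK2",
     "locus": ["LEU855", "GLY858", "ARG980", "LEU983"],
     "n_hb": {"value": 0}, "n_hydrophobic": {"value": 13},
     "affinity_kcal_mol": -8.7, "context_only": ["affinity_kcal_mol"]},
    {"ligand": "KEV", "pocket": "JAK2",
     "locus": ["LEU855", "GLY858", "ARG980", "LEU983"],
     "n_hb": {"value": 1}, "n_hydrophobic": {"value": 12},
     "affinity_kcal_mol": -8.6, "context_only": ["affinity_kcal_mol"]},
    {"ligand": "ruxolitinib", "pocket": "JAK2",
     "locus": ["LEU855", "GLY858", "ARG980", "LEU983"],
     "n_hb": {"value": 0}, "n_hydrophobic": {"value": 11, "tol": 2, "kind": "abs"},
     "affinity_kcal_mol": -8.0, "context_only": ["affinity_kcal_mol"]}
  ],
  "ligand_properties": {
    "ruxolitinib_mw": {"value": 306.4, "tol": 0.02, "kind": "rel"}
  }
}
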