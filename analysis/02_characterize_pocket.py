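#!/usr/bin/env python
"""Full pocket characterization (the single-pocket summary table).

Runs the strip -> select -> secondary structure -> SASA -> hydrogen bonds ->
composition -> contact network chain on the mixed synthetic pocket from
analysis/01, and - when the two deposited kinase structures are available at
data/pdb/6n7a.pdb and data/pdb/4yth.pdb - on the real JAK1 (865-1154) and
JAK2 (842-1130) pockets, comparing each report against the shipped published
reference values.

The deposited structures are not redistributable inside this repository;
fetch them once with e.g.
    curl -o data/pdb/6n7a.pdb https://files.rcsb.org/download/6N7A.pdb
    curl -o data/pdb/4yth.pdb https://files.rcsb.org/download/4YTH.pdb
"""

from pathlib import Path

from pocketprofiler.pipeline import RunConfig, compare_report, load_reference, run_characterization
from pocketprofiler.structure import read_pdb

FIXTURE = Path("results/fixtures/mixed_pocket.pdb")
OUT = "results/characterization"

if not FIXTURE.exists():
    raise SystemExit("run analysis/01_generate_fixtures.py first")

cfg = RunConfig(values={"output.dir": OUT})
report = run_characterization(cfg, model=read_pdb(FIXTURE), pocket_id="mixed_pocket")
print("--- synthetic mixed pocket ---")
print(f"residues={report.n_residues}  helices={report.n_helices}  strands={report.n_strands}")
print(f"SASA={report.sasa_total:.1f} A^2  H-bonds={report.n_hbonds}")
print(f"composition %: nonpolar={report.pct_nonpolar:.1f} polar={report.pct_polar:.1f} "
      f"charged={report.pct_charged:.1f}")
print(f"contacts: cross={report.n_cross_element} inside={report.n_inside_element}")

reference = load_reference()
for name, pdb_file in (("JAK1", Path("data/pdb/6n7a.pdb")), ("JAK2", Path("data/pdb/4yth.pdb"))):
    if not pdb_file.exists():
        print(f"\n{name}: {pdb_file} not present; skipping the real-structure run "
              "(see the module docstring for how to fetch it)")
        continue
    section = reference["pockets"][name]
    cfg = RunConfig(values={"input.pdb": str(pdb_file), "input.range": section["range"],
                            "output.dir": OUT})
    rep = run_characterization(cfg, pocket_id=name)
    fields = {k: v for k, v in section.items() if isinstance(v, dict) and "value" in v}
    table = compare_report(rep.to_dict(), fields)
    print(f"\n--- {name} ({section['pdb_id']}, {section['range']}) vs published values ---")
    print(table.to_string(index=False))
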