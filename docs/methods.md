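# Methods

This note documents the models, parameter choices and numerical behavior of
each pipeline stage, what the synthetic generator does and does not emulate,
and the known limitations.

## Structure model

PDB text is parsed with gemmi; on top of it the reader validates the
fixed-column coordinate fields (raising an error that names the offending
line), keeps only the first MODEL, and collapses alternate conformations per
atom name to the highest-occupancy conformer (ties: alphabetically first
altloc). Author numbering is used verbatim everywhere because pockets and
binding residues are addressed that way in the literature (ARG879, LEU983).
Elements come from columns 77–78 when present, otherwise from the atom-name
convention; hydrogens, when present, are ignored by all heavy-atom geometry.
Water and a configurable buffer list (SO4, GOL, EDO, ...) are stripped before
analysis; stripping is idempotent. When several copies of a ligand component
exist, the copy with the most atoms is used (ties: file order). Pocket
selection records residue numbers missing from the deposited range instead of
silently dropping them, so `len(pocket) == end − start + 1` holds exactly
when nothing is missing.

## Secondary structure (H/E/C)

Assignment follows the Kabsch–Sander hydrogen-bond pattern method. Amide
hydrogens are reconstructed at N + 1.01 Å along the direction of the
preceding residue's C→O bond (X-ray inputs carry no hydrogens; prolines and
chain-start residues donate nothing). Bond energy is
E = 0.084·332·(1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN) kcal/mol, a bond requiring
E < −0.5 (config `sse.energy_cutoff`); distances under 0.5 Å saturate at
−9.9. Two consecutive i→i+4 bonds make residues i..i+3 helical; parallel or
antiparallel bridge patterns mark strand residues; helix wins where both
apply. Chains are broken wherever C(i)–N(i+1) exceeds 2.5 Å, so disconnected
fixtures cannot form spurious turns. Element grouping keeps maximal runs of
length ≥ 4 (helix) / ≥ 2 (strand) — both config keys, because published
element counts depend on the post-processing minima. The three-state
collapse (no 3₁₀/π distinction, no sheet topology) matches what the pocket
summary reports. For exact reproduction of counts published with other
tools, DSSP or STRIDE output files can be loaded (`G,I→H`, `B→E`) and
override the internal assignment.

Published element counts for the JAK pockets came from a different assignment
method, so internal counts are *reported alongside* the reference values by
the comparison table rather than asserted to match exactly.

## SASA

Shrake–Rupley with a deterministic golden-spiral point shell — no randomness,
so results are exactly reproducible. Defaults: probe 1.4 Å (water), 960
points per atom, Chothia-type protein radii (C 1.87, N 1.65, O 1.40, S 1.85,
P 1.90 Å); a Bondi set is shipped as an alternative, and both are config
switches because published pocket SASA values rarely state their radii.
Carbon uses the single 1.87 Å radius; the aromatic/carbonyl refinement is
not split out since inputs carry elements, not chemical types. Neighbor
search is KD-tree limited to rᵢ + rⱼ + 2·probe. By default SASA is computed
on the pocket fragment in isolation (published pocket areas are labeled by
fragment range); `sasa.mode: chain` computes it in the context of the full
chain and sums pocket residues only.

Numerical behavior: the isolated-sphere and two-sphere closed forms are
matched within 1 % at 960 points; quadrature error decays roughly as
n_points^(−1/2). Because the point shell is fixed in the laboratory frame,
rigid-body rotation changes totals by the quadrature resolution (~0.3 % at
960 points) — invariance is a property of the limit, not of any finite point
count.

## Hydrogen bonds and polarity

Donors are backbone N (antecedent CA, PRO excluded) and side-chain N/O per
standard residue chemistry (SER OG, THR OG1, TYR OH, ASN ND2, GLN NE2, LYS
NZ, ARG NE/NH1/NH2, HIS ND1/NE2, TRP NE1); acceptors are backbone O/OXT and
side-chain O plus HIS ring nitrogens. Criteria: heavy-atom distance ≤ 3.5 Å
and antecedent–donor–acceptor angle ≥ 90°, both config keys — published
whole-pocket H-bond counts come from unnamed tools with unstated criteria, so
these are calibration knobs, not constants of nature. Backbone–backbone
pairs of sequence neighbors (|Δnumber| ≤ 1) are excluded; each atom pair is
counted once. Ligand atoms are typed by element (N and O both donate and
accept; a nitrile N is thereby an acceptor); a ligand donor's angle is
measured at its nearest bonded heavy atom (< 1.8 Å), and passes by default
when the ligand atom is isolated.

Polarity classes: nonpolar {GLY ALA VAL LEU ILE PRO MET PHE TRP}, polar
{SER THR CYS ASN GLN TYR}, charged {ASP GLU LYS ARG HIS}; the table is a
config item. Glycine is deliberately in the nonpolar set — hydrophobic-
contact analyses of kinase pockets treat GLY positions as hydrophobic
interaction sources. Composition percentages are plain count arithmetic;
after per-class rounding to one decimal they sum to 100 ± 0.8.

## Contact network and distance statistics

Contacts pair nonpolar residues at sequence separation ≥ 2 (covalently
constrained neighbors are not "contacts") whose distance under the chosen
metric is < 10 Å. The default metric is side-chain heavy-atom centroid
(GLY → CA); Cβ–Cβ and minimum-heavy-atom metrics are selectable, since no
single convention is universal and mode locations depend on it. The 10 Å
cutoff is the same distance rule used for ligand hydrophobic contacts. A
contact is *inside-element* iff both residues belong to the same
helix/strand element; coil-involving pairs count as cross-element by default
(`contacts.coil_policy: drop` removes them instead). Reported SD is the
population SD (a descriptive statistic over the full contact set).

Mode detection: the reported histogram uses 0.25 Å bins anchored at zero.
Modes, however, are found on a five-fold finer histogram smoothed with a
0.08 Å Gaussian kernel and scanned with scipy's peak finder using a
prominence floor of 5 % of the tallest peak. A coarse-bin moving average was
considered and rejected: maxima ~0.6 Å apart land two to three 0.25 Å bins
from each other, and any 3-bin average provably merges them into one plateau
(expected counts 222/199/199/222 become 165/207/207/165), so it cannot
resolve exactly the bimodality this analysis is about. The kernel width is
kept well below the ~0.2 Å component spread of packed-pocket contact
distances; the prominence floor suppresses sampling noise. On the reference
simulation (1000 draws from an equal mixture at 7.7/8.3 Å, SD 0.2 Å) the
detector recovers both modes within one 0.25 Å bin across 500 seeds.

## Ligand profiles

Hydrophobic contact distance is the minimum heavy-atom pair distance (ligand
atoms are individually resolved), with a centroid alternative; the < 10 Å
count includes only nonpolar-classified residues. The binding locus is the
k = 4 residues with smallest minimum distance to the ligand drawn from *all*
pocket residues — polar and charged residues (e.g. an arginine) can anchor a
ligand without being part of the hydrophobic count. Ties break toward the
lower residue number. The interaction sweep is one row per interaction
(type, residue, atoms for H-bonds, distance), sorted by type then distance —
a tabular replacement for 2D interaction diagrams. No docking is performed;
poses come from deposited HETATM records or user-supplied files.

## Alignment

For two sequences, Needleman–Wunsch with BLOSUM62 and affine gaps (open 10,
extend 0.5, terminal gaps penalized) is the standard equivalent of a Clustal
run; Biopython's PairwiseAligner provides the optimal alignment with a
deterministic traceback, verified against exhaustive enumeration of all
alignments on short sequences. Identity uses the shorter-sequence
denominator (for near-equal pocket lengths like 290/289 the choice is nearly
moot, but it is fixed and documented; `alignment_length` is available).
Conservation symbols use the canonical Clustal strong/weak group lists,
shipped as editable data. Published pocket identity (~54 % for the two JAK
pockets) was produced with unstated gap parameters, so the comparison table
treats it as a tolerance target (± 3 points), not an exact value.

## Synthetic generator

The generator emulates the statistical structure the pipeline measures on
real pockets: mixed α/β content (ideal helices — Cα exactly on the
parameterized helix with radius 2.3 Å, rise 1.5 Å, twist 100°/residue, N/C/O
from frozen ideal-geometry offsets in the local Cα frame — and antiparallel
strand pairs whose ladder satisfies the Kabsch–Sander criterion at 4.8 Å
separation), nonpolar contacts planted at exact centroid distances (within
0.05 Å, solved by anchored placement + least squares; infeasible constraint
sets raise an error), ligands as compact atom clusters with residues pinned
at exact minimum heavy-atom distances (bisection to ±0.02 Å), and hydrogen
bonds planted at controlled distance/angle with partner atoms placed outward
from the residue body so no incidental geometry arises. Unconstrained
residues scatter on a 14 Å grid — beyond every cutoff. All randomness flows
from one seed; identical spec + seed gives byte-identical PDB output, and
optional coordinate noise (SD ≤ 0.2 Å, clipped at 2 SD) is applied last.

What it does **not** emulate: real rotamer distributions, realistic packing
densities, ligand chemistry beyond element typing, crystallographic disorder
or missing loops. Passing tests therefore demonstrate that the measurements
are computed correctly — exact bookkeeping, closed-form and oracle
agreement, planted-truth recovery — not that any particular published value
for a real structure will be reproduced; real-structure comparisons run
through `analysis/02`–`05` and the `compare` command when the deposited
files are supplied, with per-field tolerances carried by the shipped
reference table.

## Problem sizes and determinism

Default test and analysis problem sizes are chosen for seconds-scale runs on
one CPU: pockets of 10–40 synthetic residues, 100-seed randomized fixture
sweeps, 960-point SASA quadrature, 1000-draw mixture simulations. Real
pockets (≈290 residues, ≈2300 heavy atoms) characterize in ~10 s. Every
stage is deterministic given its inputs and config; reports embed the full
resolved configuration so each number traces to its parameters.

## Known limitations

* Internal secondary-structure counts can differ from other assignment
  methods near element boundaries; use an external DSSP/STRIDE file for
  method-exact reproduction.
* Whole-pocket H-bond counts are sensitive to the distance/angle criteria;
  defaults are common practice, not a standard.
* The ligand H-bond typing by element cannot distinguish hydroxyl from
  carbonyl oxygens without connectivity; both directions are allowed, with
  deduplication per atom pair.
* mmCIF, symmetry mates, anisotropic records and hydrogen placement are out
  of scope; single-conformer, first-MODEL geometry only.
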