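"""Orchestration: full pocket characterization and ligand profiling runs.

A run is driven by a flat, namespaced key space (``sasa.probe``,
``contacts.cutoff``, ...) read from JSON or YAML; unknown keys are rejected
and every key has a documented default, and the full resolved configuration
is echoed into each report so every number traces to its parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import geometry as geo
from . import sasa as sa
from . import secondary as ss
from . import structure as st
from .ligand import build_profile, interaction_sweep

__all__ = [
    "RunConfig",
    "PocketReport",
    "run_characterization",
    "run_ligand_profiles",
    "compare_report",
    "load_reference",
]

log = logging.getLogger("pocketprofiler")

DEFAULTS: dict[str, object] = {
    "input.pdb": None,
    "input.chain": None,  # None: first polymer chain in file order
    "input.range": None,  # "START:END" author numbering
    "input.ligands": [],  # hetcodes to profile
    "input.strip": sorted(st.DEFAULT_STRIP),
    "sse.min_helix": 4,
    "sse.min_strand": 2,
    "sse.energy_cutoff": -0.5,
    "sse.external_file": None,  # DSSP/STRIDE output overriding the internal assignment
    "sasa.probe": 1.4,
    "sasa.n_points": 960,
    "sasa.radii_set": "chothia",
    "sasa.mode": "fragment",  # fragment | chain
    "hbonds.d_max": 3.5,
    "hbonds.angle_min": 90.0,
    "contacts.cutoff": 10.0,
    "contacts.metric": "sidechain_centroid",
    "contacts.coil_policy": "cross",
    "contacts.bin_width": 0.25,
    "ligand.cutoff": 10.0,
    "ligand.locus_k": 4,
    "align.matrix": "BLOSUM62",
    "align.gap_open": 10.0,
    "align.gap_extend": 0.5,
    "align.denominator": "shorter_sequence_length",
    "output.dir": None,
    "seed": 0,
}


@dataclass
class RunConfig:
    values: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(DEFAULTS)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    @property
    def pocket_range(self) -> tuple[int, int] | None:
        r = self.values["input.range"]
        if r is None:
            return None
        start, end = str(r).split(":")
        return int(start), int(end)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(values=data or {})

    def echo(self) -> dict[str, object]:
        return {k: self.values[k] for k in sorted(self.values)}


@dataclass
class PocketReport:
    pocket_id: str
    n_residues: int
    missing_residues: int
    first_residue: str
    last_residue: str
    sasa_total: float
    n_hbonds: int
    pct_nonpolar: float
    pct_polar: float
    pct_charged: float
    n_helices: int
    n_strands: int
    n_cross_element: int
    n_inside_element: int
    cross_mean: float | None
    cross_sd: float | None
    inside_mean: float | None
    inside_sd: float | None
    cross_modes: list[float]
    inside_modes: list[float]
    config: dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict[str, object]:
        def clean(v):
            if isinstance(v, float):
                return round(v, 4)
            if isinstance(v, list):
                return [clean(x) for x in v]
            return v

        return {k: clean(v) for k, v in self.__dict__.items()}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _load_pocket(config: RunConfig, model: st.StructureModel | None):
    if model is None:
        pdb = config["input.pdb"]
        if pdb is None:
            raise ValueError("characterization stage: no input structure (input.pdb unset)")
        model = st.read_pdb(pdb)
    model = st.strip_non_structural(model, set(config["input.strip"]))
    rng = config.pocket_range
    chain = config["input.chain"] or model.first_chain_id()
    if rng is None:
        numbers = [r.number for r in model.chains[chain]]
        rng = (min(numbers), max(numbers))
    return model, st.select_pocket(model, chain, rng[0], rng[1])


def _annotate(pocket, config: RunConfig):
    external = config["sse.external_file"]
    if external:
        ann = ss.apply_external(pocket, ss.load_external_sse(Path(external).read_text()))
    else:
        ann = ss.assign_sse(pocket, energy_cutoff=float(config["sse.energy_cutoff"]))
    elements = ss.group_elements(ann, min_len_H=int(config["sse.min_helix"]),
                                 min_len_E=int(config["sse.min_strand"]))
    return ann, elements


def run_characterization(config: RunConfig, model: st.StructureModel | None = None,
                         pocket_id: str = "pocket") -> PocketReport:
    """Execute the full characterization chain: strip -> select pocket ->
    secondary structure -> SASA -> hydrogen bonds -> composition -> nonpolar
    contact network -> distance statistics.  Writes TSV + JSON when
    ``output.dir`` is set."""
    log.info("characterization parameters: %s", config.echo())
    model, pocket = _load_pocket(config, model)
    ann, elements = _annotate(pocket, config)

    sasa_kwargs = dict(probe_radius=float(config["sasa.probe"]),
                       n_points=int(config["sasa.n_points"]),
                       radii=str(config["sasa.radii_set"]))
    if config["sasa.mode"] == "chain":
        sasa = sa.pocket_sasa_in_context(pocket, **sasa_kwargs)
    else:
        sasa = sa.pocket_sasa(pocket, **sasa_kwargs)

    hbonds = geo.detect_hbonds(pocket, d_max=float(config["hbonds.d_max"]),
                               angle_min=float(config["hbonds.angle_min"]))
    comp = geo.composition(pocket)
    contacts = geo.nonpolar_contact_network(
        pocket, elements,
        cutoff=float(config["contacts.cutoff"]),
        metric=str(config["contacts.metric"]),
        coil_policy=str(config["contacts.coil_policy"]),
    )
    bw = float(config["contacts.bin_width"])
    cross = geo.contact_statistics(contacts, "cross-element", bin_width=bw)
    inside = geo.contact_statistics(contacts, "inside-element", bin_width=bw)

    report = PocketReport(
        pocket_id=pocket_id,
        n_residues=len(pocket),
        missing_residues=len(pocket.missing_numbers),
        first_residue=pocket.residues[0].name,
        last_residue=pocket.residues[-1].name,
        sasa_total=sasa.total,
        n_hbonds=len(hbonds),
        pct_nonpolar=comp.percentages["nonpolar"],
        pct_polar=comp.percentages["polar"],
        pct_charged=comp.percentages["charged"],
        n_helices=sum(1 for e in elements if e.state == "H"),
        n_strands=sum(1 for e in elements if e.state == "E"),
        n_cross_element=contacts.count("cross-element"),
        n_inside_element=contacts.count("inside-element"),
        cross_mean=cross.mean, cross_sd=cross.sd,
        inside_mean=inside.mean, inside_sd=inside.sd,
        cross_modes=cross.modes, inside_modes=inside.modes,
        config=config.echo(),
    )

    outdir = config["output.dir"]
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"{pocket_id}_report.json").write_text(report.to_json() + "\n")
        rows = [{"residue_a": c.residue_a.label, "residue_b": c.residue_b.label,
                 "distance": round(c.distance, 3), "kind": c.kind,
                 "element_a": c.element_a, "element_b": c.element_b}
                for c in contacts.contacts]
        pd.DataFrame(rows, columns=["residue_a", "residue_b", "distance", "kind",
                                    "element_a", "element_b"]).to_csv(
            outdir / f"{pocket_id}_contacts.tsv", sep="\t", index=False)
        hb_rows = [{"donor": f"{b.donor_residue.label}:{b.donor_atom.name}",
                    "acceptor": f"{b.acceptor_residue.label}:{b.acceptor_atom.name}",
                    "distance": round(b.distance, 3), "angle": round(b.angle, 1)}
                   for b in hbonds]
        pd.DataFrame(hb_rows, columns=["donor", "acceptor", "distance", "angle"]).to_csv(
            outdir / f"{pocket_id}_hbonds.tsv", sep="\t", index=False)
    return report


def run_ligand_profiles(config: RunConfig, model: st.StructureModel | None = None,
                        pocket_id: str = "pocket") -> pd.DataFrame:
    """One interaction profile per configured ligand hetcode; a missing
    ligand marks its row failed and the run continues."""
    log.info("ligand profiling parameters: %s", config.echo())
    model, pocket = _load_pocket(config, model)
    rows = []
    outdir = Path(config["output.dir"]) if config["output.dir"] else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    for hetcode in config["input.ligands"]:
        try:
            lig = st.extract_ligand(model, hetcode)
        except (KeyError, ValueError) as exc:
            log.warning("ligand %s failed: %s", hetcode, exc)
            rows.append({"ligand": hetcode, "pocket": pocket_id, "locus": "",
                         "n_hb": None, "n_hydrophobic": None, "status": "failed"})
            continue
        profile = build_profile(
            pocket, lig,
            cutoff=float(config["ligand.cutoff"]),
            d_max=float(config["hbonds.d_max"]),
            angle_min=float(config["hbonds.angle_min"]),
            locus_k=int(config["ligand.locus_k"]),
        )
        rows.append({
            "ligand": hetcode,
            "pocket": pocket_id,
            "locus": ",".join(r.label for r in sorted(profile.locus_residues, key=lambda r: r.number)),
            "n_hb": profile.n_hb,
            "n_hydrophobic": profile.n_hydrophobic,
            "status": "ok",
        })
        if outdir:
            interaction_sweep(profile).to_csv(
                outdir / f"{pocket_id}_{hetcode}_sweep.tsv", sep="\t", index=False)
    table = pd.DataFrame(rows, columns=["ligand", "pocket", "locus", "n_hb", "n_hydrophobic", "status"])
    if outdir:
        table.to_csv(outdir / f"{pocket_id}_ligand_profiles.tsv", sep="\t", index=False)
    return table


# ---------------------------------------------------------------------------
# comparison against a published-values reference file

def load_reference(path=None) -> dict:
    """Reference values (and tolerances) for the JAK1/JAK2 pockets shipped
    with the package; affinity energies are context-only and never compared."""
    if path is None:
        path = Path(__file__).parent / "data" / "jak_reference.json"
    return json.loads(Path(path).read_text())


def compare_report(report: dict, reference_fields: dict) -> pd.DataFrame:
    """Per-field deviation of a report against reference entries of the form
    ``{"value": v, "tol": t, "kind": "abs"|"rel"}``."""
    rows = []
    for name, ref in reference_fields.items():
        if not isinstance(ref, dict) or "value" not in ref:
            raise ValueError(f"reference field {name!r} is not schema-valid")
        ref_value = ref["value"]
        got = report.get(name)
        if got is None:
            rows.append({"field": name, "reported": None, "reference": ref_value,
                         "abs_dev": None, "rel_dev": None, "status": "unavailable"})
            continue
        if isinstance(ref_value, str) or isinstance(got, str):
            rows.append({"field": name, "reported": got, "reference": ref_value,
                         "abs_dev": None, "rel_dev": None,
                         "status": "pass" if str(got) == str(ref_value) else "fail"})
            continue
        abs_dev = abs(float(got) - float(ref_value))
        rel_dev = abs_dev / abs(float(ref_value)) if ref_value else float("inf")
        status = ""
        if "tol" in ref:
            dev = abs_dev if ref.get("kind", "abs") == "abs" else rel_dev
            status = "pass" if dev <= ref["tol"] else "fail"
        rows.append({"field": name, "reported": got, "reference": ref_value,
                     "abs_dev": round(abs_dev, 6), "rel_dev": round(rel_dev, 6),
                     "status": status})
    return pd.DataFrame(rows, columns=["field", "reported", "reference", "abs_dev", "rel_dev", "status"])
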