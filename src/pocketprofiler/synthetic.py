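"""Synthetic structures with known ground truth.

Everything the analysis stages measure on real kinase pockets can be planted
here by construction: ideal helices and antiparallel strand pairs for the
secondary-structure stage, toy pockets with residue centroids fixed at chosen
pair distances for the contact network, and toy protein-ligand complexes with
planted hydrogen-bond geometries and ligand proximity shells.  Fixtures are
emitted as ordinary PDB text and consumed through the normal reader, so the
pipeline is exercised end to end.

All randomness flows from the single ``seed`` of a :class:`SyntheticSpec`;
identical spec + seed yields byte-identical PDB output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Atom, Residue, StructureModel, write_pdb

__all__ = [
    "SyntheticSpec",
    "LigandPlan",
    "PlantedHBond",
    "PlacementError",
    "ideal_helix",
    "ideal_strand_pair",
    "extended_chain",
    "toy_complex",
    "residues_to_model",
]


class PlacementError(ValueError):
    """Planted geometric constraints cannot be satisfied."""


# ---------------------------------------------------------------------------
# backbone construction by internal coordinates (NeRF)

# ideal peptide geometry (lengths in A, angles in degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8

# N/C/O offsets of an ideal alpha-helix expressed in the orthonormal frame
# spanned by consecutive Ca triples (e1 along Ca(i-1)->Ca(i+1), e2 toward the
# local curvature center); derived once from the internal-coordinate helix
# with phi=-57.8, psi=-47.0 and frozen.
_HELIX_FRAME_OFFSETS = {
    "N": np.array([-1.0960, 0.8923, -0.3582]),
    "C": np.array([1.2263, 0.7863, 0.4513]),
    "O": np.array([1.8344, 0.4730, 1.4747]),
}

# antiparallel partner placement for ideal_strand_pair: 180 deg rotation about
# the y axis plus a register shift along the strand axis, calibrated so the
# Kabsch-Sander criterion detects the inter-strand ladder at 4.8 A separation.
_STRAND_PARTNER_ROT = np.diag([-1.0, 1.0, -1.0])
_STRAND_REGISTER_DX = -1.3


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, dihedral: float) -> np.ndarray:
    angle, dihedral = np.radians(angle), np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.cos(dihedral) * np.sin(angle),
                  bond * np.sin(dihedral) * np.sin(angle)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _backbone_chain(n: int, phi: float, psi: float, omega: float = 180.0) -> dict[str, np.ndarray]:
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    CA[0] = [_B_N_CA, 0.0, 0.0]
    ang = np.radians(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n):
        if i > 0:
            N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi)
            CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, omega)
            C[i] = _place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi)
        O[i] = _place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def _bb_to_residues(bb: dict[str, np.ndarray], residue_name: str, chain_id: str,
                    start: int, serial0: int = 1) -> list[Residue]:
    residues = []
    serial = serial0
    for i in range(len(bb["CA"])):
        atoms = []
        for name in ("N", "CA", "C", "O"):
            atoms.append(Atom(serial=serial, name=name, element=name[0],
                              coords=bb[name][i].copy()))
            serial += 1
        residues.append(Residue(name=residue_name, number=start + i,
                                chain_id=chain_id, atoms=atoms))
    return residues


def ideal_helix(n: int, radius: float = 2.3, rise: float = 1.5, twist: float = 100.0,
                chain_id: str = "A", start: int = 1, residue_name: str = "ALA") -> list[Residue]:
    """Backbone of an ideal alpha-helix.

    Ca atoms sit exactly on the parameterized helix
    ``(radius cos(i*twist), radius sin(i*twist), i*rise)``, so the consecutive
    Ca-Ca distance is ``sqrt((2 radius sin(twist/2))^2 + rise^2)`` (3.83 A at
    the defaults).  N, C and O are placed from frozen ideal-geometry offsets in
    the local Ca frame, which reproduces Kabsch-Sander detectable i -> i+4
    hydrogen bonds at the default parameters.
    """
    if n < 1:
        raise ValueError("helix needs at least one residue")
    idx = np.arange(-1, n + 1)  # virtual flanking Ca for terminal frames
    theta = np.radians(twist) * idx
    ca_ext = np.stack([radius * np.cos(theta), radius * np.sin(theta), rise * idx], axis=1)
    bb = {name: np.zeros((n, 3)) for name in ("N", "CA", "C", "O")}
    bb["CA"] = ca_ext[1:-1]
    for j in range(1, n + 1):
        e1 = ca_ext[j + 1] - ca_ext[j - 1]
        e1 /= np.linalg.norm(e1)
        v = ca_ext[j - 1] + ca_ext[j + 1] - 2 * ca_ext[j]
        e2 = v - (v @ e1) * e1
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        frame = np.stack([e1, e2, e3])
        for name in ("N", "C", "O"):
            bb[name][j - 1] = ca_ext[j] + frame.T @ _HELIX_FRAME_OFFSETS[name]
    return _bb_to_residues(bb, residue_name, chain_id, start)


def _rotation_to_x(u: np.ndarray) -> np.ndarray:
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(u, x)
    s = np.linalg.norm(v)
    c = float(u @ x)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def extended_chain(n: int, phi: float = 180.0, psi: float = 180.0,
                   chain_id: str = "A", start: int = 1,
                   residue_name: str = "ALA") -> list[Residue]:
    """Fully extended (default) or beta-dihedral single chain, axis along +x."""
    bb = _backbone_chain(n, phi=phi, psi=psi)
    ca = bb["CA"]
    rot = _rotation_to_x((ca[-1] - ca[0]) / np.linalg.norm(ca[-1] - ca[0]))
    center = ca.mean(axis=0)
    bb = {k: (v - center) @ rot.T for k, v in bb.items()}
    return _bb_to_residues(bb, residue_name, chain_id, start)


def ideal_strand_pair(n: int, separation: float = 4.8,
                      residue_name: str = "ALA", start: int = 1) -> list[Residue]:
    """Two antiparallel beta strands (chains A and B, ``2n`` residues total)
    whose inter-strand H-bond ladder satisfies the Kabsch-Sander criterion at
    the default 4.8 A separation."""
    if n < 2:
        raise ValueError("strand pair needs at least two residues per strand")
    bb = _backbone_chain(n, phi=-139.0, psi=135.0)
    ca = bb["CA"]
    rot = _rotation_to_x((ca[-1] - ca[0]) / np.linalg.norm(ca[-1] - ca[0]))
    center = ca.mean(axis=0)
    a = {k: (v - center) @ rot.T for k, v in bb.items()}
    shift = np.array([_STRAND_REGISTER_DX, separation, 0.0])
    b = {k: v @ _STRAND_PARTNER_ROT.T + shift for k, v in a.items()}
    res_a = _bb_to_residues(a, residue_name, "A", start)
    res_b = _bb_to_residues(b, residue_name, "B", start, serial0=4 * n + 1)
    return res_a + res_b


def residues_to_model(residues: list[Residue], source_id: str = "synthetic") -> StructureModel:
    model = StructureModel(source_id=source_id)
    for r in residues:
        model.chains.setdefault(r.chain_id, []).append(r)
    return model


# ---------------------------------------------------------------------------
# residue templates for toy pockets (local coordinates, CA at origin)

def _chainlet(names_elements, start_vec, step=1.52):
    """Side-chain atoms strung outward from CB in a fixed direction."""
    out = []
    pos = np.array(start_vec, dtype=float)
    direction = np.array([0.25, -0.35, 0.9])
    direction /= np.linalg.norm(direction)
    for k, (name, element) in enumerate(names_elements):
        out.append((name, element, pos + k * step * direction))
    return out


_BB = [("N", "N", np.array([-1.458, 0.0, 0.0])),
       ("CA", "C", np.array([0.0, 0.0, 0.0])),
       ("C", "C", np.array([0.551, 1.422, 0.0])),
       ("O", "O", np.array([1.421, 1.697, 0.836]))]
_CB = np.array([0.50, -0.78, 1.20])

RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, np.ndarray]]] = {
    "GLY": list(_BB),
    "ALA": _BB + [("CB", "C", _CB)],
    "VAL": _BB + [("CB", "C", _CB),
                  ("CG1", "C", _CB + [1.25, -0.45, 0.75]),
                  ("CG2", "C", _CB + [-1.05, -0.75, 0.85])],
    "LEU": _BB + _chainlet([("CB", "C"), ("CG", "C")], _CB) +
           [("CD1", "C", _CB + [1.45, -0.75, 1.95]), ("CD2", "C", _CB + [-0.95, -1.05, 1.95])],
    "SER": _BB + _chainlet([("CB", "C"), ("OG", "O")], _CB, step=1.42),
    "CYS": _BB + _chainlet([("CB", "C"), ("SG", "S")], _CB, step=1.81),
    "THR": _BB + [("CB", "C", _CB),
                  ("OG1", "O", _CB + [1.15, -0.45, 0.80]),
                  ("CG2", "C", _CB + [-1.05, -0.75, 0.85])],
    "ASN": _BB + _chainlet([("CB", "C"), ("CG", "C")], _CB) +
           [("OD1", "O", _CB + [1.35, -0.85, 1.95]), ("ND2", "N", _CB + [-0.85, -1.15, 1.95])],
    "ASP": _BB + _chainlet([("CB", "C"), ("CG", "C")], _CB) +
           [("OD1", "O", _CB + [1.35, -0.85, 1.95]), ("OD2", "O", _CB + [-0.85, -1.15, 1.95])],
    "MET": _BB + _chainlet([("CB", "C"), ("CG", "C"), ("SD", "S"), ("CE", "C")], _CB),
    "LYS": _BB + _chainlet([("CB", "C"), ("CG", "C"), ("CD", "C"), ("CE", "C"), ("NZ", "N")], _CB),
    "ARG": _BB + _chainlet([("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"), ("CZ", "C")], _CB) +
           [("NH1", "N", _CB + [1.55, -1.25, 4.75]), ("NH2", "N", _CB + [-0.75, -1.65, 4.85])],
}

_DEFAULT_CYCLE = ["LEU", "SER", "ASP", "GLY", "VAL", "ASN", "ARG", "ALA"]


def _template_residue(name: str, number: int, chain_id: str, serial0: int) -> Residue:
    if name not in RESIDUE_TEMPLATES:
        raise KeyError(f"no synthetic template for residue {name!r}; have {sorted(RESIDUE_TEMPLATES)}")
    atoms = [Atom(serial=serial0 + k, name=an, element=el, coords=np.array(pos, dtype=float))
             for k, (an, el, pos) in enumerate(RESIDUE_TEMPLATES[name])]
    return Residue(name=name, number=number, chain_id=chain_id, atoms=atoms)


# ---------------------------------------------------------------------------
# toy complexes

@dataclass
class LigandPlan:
    """Toy ligand: a compact heavy-atom cluster at the origin plus the pocket
    residues that must sit at given minimum heavy-atom distances from it."""

    n_atoms: int = 5
    near: list[tuple[int, float]] = field(default_factory=list)  # (residue index, min distance A)
    elements: list[str] | None = None  # per-atom elements; default C with one N


@dataclass
class PlantedHBond:
    """One protein-ligand hydrogen bond planted at controlled geometry."""

    residue_index: int
    protein_atom: str = "O"  # acceptor O (ligand donates) or donor N/OG (ligand accepts)
    ligand_is_donor: bool = True
    distance: float = 2.9  # donor-acceptor heavy-atom distance, A
    angle: float = 160.0  # antecedent-donor-acceptor angle, deg


@dataclass
class SyntheticSpec:
    n_residues: int
    residue_names: list[str] | None = None
    element_plan: list[tuple[str, int]] | None = None  # (H|E|C, length)
    planted_contacts: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    planted_hbonds: list[PlantedHBond] = field(default_factory=list)
    ligand_plan: LigandPlan | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.element_plan is not None:
            total = sum(length for _, length in self.element_plan)
            if total != self.n_residues:
                raise ValueError(f"element_plan lengths sum to {total}, expected {self.n_residues}")


def _golden_directions(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1 - 2 * i / n
    phi = i * np.pi * (3 - np.sqrt(5))
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _grid_positions(count: int, origin: np.ndarray, spacing: float = 14.0) -> list[np.ndarray]:
    out = []
    k = 0
    side = int(np.ceil(count ** (1 / 3))) or 1
    for ix in range(side + 1):
        for iy in range(side + 1):
            for iz in range(side + 1):
                if k >= count:
                    return out
                out.append(origin + spacing * np.array([ix, iy, iz], dtype=float))
                k += 1
    return out


def _solve_position(anchors: list[tuple[np.ndarray, float]], rng: np.random.Generator) -> np.ndarray:
    """Point at given distances from anchor points (1-3+ constraints)."""
    if len(anchors) == 1:
        p, d = anchors[0]
        return p + d * _random_unit(rng)
    # least squares from a reasonable start, then verify outside
    from scipy.optimize import least_squares

    start = np.mean([p for p, _ in anchors], axis=0) + _random_unit(rng)

    def resid(x):
        return [np.linalg.norm(x - p) - d for p, d in anchors]

    sol = least_squares(resid, start)
    return sol.x


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perpendicular_seed(u: np.ndarray) -> np.ndarray:
    """A deterministic vector not parallel to u (for building perpendiculars)."""
    return np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])


def _min_heavy_distance(res: Residue, ligand_coords: np.ndarray) -> float:
    rc = res.heavy_coords()
    d = np.linalg.norm(rc[:, None, :] - ligand_coords[None, :, :], axis=2)
    return float(d.min())


def _translate(res: Residue, vec: np.ndarray) -> None:
    for a in res.atoms:
        a.coords = a.coords + vec


def toy_complex(spec: SyntheticSpec) -> StructureModel:
    """Build a toy pocket (optionally with a ligand) honoring the planted
    ground truth of ``spec``.

    Residue side-chain centroids obey ``planted_contacts`` pair distances to
    within 0.05 A; ``ligand_plan.near`` residues sit at their stated minimum
    heavy-atom distance from the ligand (+-0.02 A); planted hydrogen bonds get
    dedicated donor/acceptor atom pairs at the stated distance and angle.
    Everything else is scattered far apart (grid spacing 14 A) so no
    accidental contacts arise.  Raises :class:`PlacementError` when the
    planted constraints cannot all be met.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    names = spec.residue_names or [_DEFAULT_CYCLE[i % len(_DEFAULT_CYCLE)] for i in range(n)]
    if len(names) != n:
        raise ValueError("residue_names length != n_residues")

    if spec.element_plan is not None:
        return _structured_pocket(spec, names)

    residues: list[Residue] = []
    serial = 1
    for i in range(n):
        res = _template_residue(names[i], i + 1, "A", serial)
        serial += len(res.atoms)
        residues.append(res)

    ligand_atoms: list[Atom] = []
    hetatm_serial = 9000

    # ligand cluster at the origin
    if spec.ligand_plan is not None:
        lp = spec.ligand_plan
        elements = lp.elements or (["C"] * (lp.n_atoms - 1) + ["N"] if lp.n_atoms > 1 else ["C"])
        if len(elements) != lp.n_atoms:
            raise ValueError("ligand elements length != n_atoms")
        dirs = _golden_directions(max(lp.n_atoms - 1, 1))
        coords = [np.zeros(3)] + [1.45 * dirs[k] for k in range(lp.n_atoms - 1)]
        for el, pos in zip(elements, coords):
            ligand_atoms.append(Atom(serial=hetatm_serial, name=f"{el}{len(ligand_atoms)+1}",
                                     element=el, coords=pos, record="HETATM"))
            hetatm_serial += 1

    placed: dict[int, np.ndarray] = {}  # residue index -> centroid position

    # residues pinned near the ligand at exact minimum heavy-atom distances
    ray_constraints = list(spec.ligand_plan.near) if spec.ligand_plan else []
    hb_only = [hb.residue_index for hb in spec.planted_hbonds
               if hb.residue_index not in {i for i, _ in ray_constraints}]
    ray_constraints += [(i, 5.0) for i in hb_only]
    if ray_constraints:
        if spec.ligand_plan is None and spec.planted_hbonds:
            # hydrogen bonds planted without a ligand plan still need a ligand
            ligand_atoms.append(Atom(serial=hetatm_serial, name="C1", element="C",
                                     coords=np.zeros(3), record="HETATM"))
            hetatm_serial += 1
        lig_coords = np.array([a.coords for a in ligand_atoms])
        dirs = _golden_directions(len(ray_constraints))
        for (idx, target), direction in zip(ray_constraints, dirs):
            res = residues[idx]
            centroid0 = res.sidechain_centroid()
            lo, hi = max(target - 4.0, 0.1), target + 12.0

            def mindist(rho):
                offset = rho * direction - centroid0
                rc = res.heavy_coords() + offset
                return np.linalg.norm(rc[:, None, :] - lig_coords[None, :, :], axis=2).min()

            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if mindist(mid) < target:
                    lo = mid
                else:
                    hi = mid
            rho = 0.5 * (lo + hi)
            if abs(mindist(rho) - target) > 0.02:
                raise PlacementError(
                    f"cannot place residue {idx} at min distance {target} from ligand")
            _translate(res, rho * direction - centroid0)
            placed[idx] = res.sidechain_centroid()

    # planted residue-residue centroid distances, per connected component
    if spec.planted_contacts:
        adj: dict[int, list[tuple[int, float]]] = {}
        for (i, j), d in spec.planted_contacts:
            adj.setdefault(i, []).append((j, d))
            adj.setdefault(j, []).append((i, d))
        component_origin = np.array([60.0, 0.0, 0.0])
        comp_slots = _grid_positions(len(adj), component_origin, spacing=40.0)
        slot = 0
        for root in sorted(adj):
            if root in placed:
                continue
            placed[root] = comp_slots[slot]
            slot += 1
            queue = [root]
            while queue:
                cur = queue.pop(0)
                for nbr, _ in sorted(adj[cur]):
                    if nbr in placed:
                        continue
                    anchors = [(placed[k], dk) for k, dk in sorted(adj[nbr]) if k in placed]
                    placed[nbr] = _solve_position(anchors, rng)
                    queue.append(nbr)
        for (i, j), d in spec.planted_contacts:
            got = np.linalg.norm(placed[i] - placed[j])
            if abs(got - d) > 0.05:
                raise PlacementError(
                    f"planted contact ({i},{j}) at {d} A infeasible (achieved {got:.3f} A)")
        for idx in adj:
            res = residues[idx]
            _translate(res, placed[idx] - res.sidechain_centroid())

    # everything unconstrained goes on a far grid
    loose = [i for i in range(n) if i not in placed]
    for idx, pos in zip(loose, _grid_positions(len(loose), np.array([-40.0, -200.0, 0.0]))):
        res = residues[idx]
        _translate(res, pos - res.sidechain_centroid())
        placed[idx] = pos

    # planted hydrogen bonds: ligand partner atoms at controlled geometry
    for hb in spec.planted_hbonds:
        res = residues[hb.residue_index]
        patom = res.atom(hb.protein_atom)
        if patom is None:
            raise PlacementError(f"residue {hb.residue_index} has no atom {hb.protein_atom}")
        if hb.ligand_is_donor:
            # ligand N donates to the protein acceptor; it is placed outward
            # (away from the residue body) so no incidental geometry arises,
            # and its antecedent C sets the angle
            centroid = res.heavy_coords().mean(axis=0)
            direction = patom.coords - centroid
            if np.linalg.norm(direction) < 1e-6:
                direction = _random_unit(rng)
            direction = direction / np.linalg.norm(direction)
            donor_pos = patom.coords + hb.distance * direction
            u = (patom.coords - donor_pos) / hb.distance
            perp = np.cross(u, _perpendicular_seed(u))
            perp /= np.linalg.norm(perp)
            theta = np.radians(hb.angle)
            ante_pos = donor_pos + 1.45 * (np.cos(theta) * u + np.sin(theta) * perp)
            ligand_atoms.append(Atom(serial=hetatm_serial, name=f"N{len(ligand_atoms)+1}",
                                     element="N", coords=donor_pos, record="HETATM"))
            hetatm_serial += 1
            ligand_atoms.append(Atom(serial=hetatm_serial, name=f"C{len(ligand_atoms)+1}",
                                     element="C", coords=ante_pos, record="HETATM"))
            hetatm_serial += 1
        else:
            # protein donor; ligand O acceptor placed at the stated angle from
            # the donor's own antecedent
            ante_name = {"N": "CA", "OG": "CB", "OG1": "CB", "ND2": "CG", "NZ": "CE"}.get(
                hb.protein_atom, "CA")
            ante = res.atom(ante_name)
            if ante is None:
                raise PlacementError(f"donor antecedent {ante_name} missing")
            u = (ante.coords - patom.coords)
            u /= np.linalg.norm(u)
            perp = np.cross(u, _perpendicular_seed(u))
            perp /= np.linalg.norm(perp)
            theta = np.radians(hb.angle)
            acc_pos = patom.coords + hb.distance * (np.cos(theta) * u + np.sin(theta) * perp)
            ligand_atoms.append(Atom(serial=hetatm_serial, name=f"O{len(ligand_atoms)+1}",
                                     element="O", coords=acc_pos, record="HETATM"))
            hetatm_serial += 1

    # bounded coordinate noise, applied last
    if spec.noise_sigma > 0:
        cap = 2.0 * spec.noise_sigma
        for res in residues:
            for a in res.atoms:
                a.coords = a.coords + np.clip(
                    rng.normal(0.0, spec.noise_sigma, size=3), -cap, cap)

    model = residues_to_model(residues, source_id=f"toy_complex(seed={spec.seed})")
    if ligand_atoms:
        model.hetero_groups[("LIG", "A", 900)] = ligand_atoms
    return model


def _structured_pocket(spec: SyntheticSpec, names: list[str]) -> StructureModel:
    """Pocket with a prescribed secondary-structure plan: H segments are ideal
    helices, consecutive E segments pair up as antiparallel strands, C
    segments are fully extended coil.  Segments are placed on a coarse grid so
    only the planned intra-segment geometry produces structure."""
    segments: list[tuple[str, int]] = list(spec.element_plan or [])
    residues: list[Residue] = []
    number = 1
    pending_strand: tuple[int, int] | None = None  # (start number, length) awaiting its partner
    region = 0

    def region_offset() -> np.ndarray:
        nonlocal region
        off = np.array([0.0, 26.0 * region, 0.0])
        region += 1
        return off

    for state, length in segments:
        if state == "H":
            seg = ideal_helix(length, start=number)
        elif state == "E":
            if pending_strand is None:
                pending_strand = (number, length)
                number += length
                continue
            s0, l0 = pending_strand
            m = min(l0, length)
            pair = ideal_strand_pair(max(m, 2), start=1)
            first, second = pair[: max(m, 2)], pair[max(m, 2):]
            seg = []
            off = region_offset()
            for k in range(l0):
                src = first[min(k, len(first) - 1)]
                seg.append(_renumber(src, s0 + k, "A", off))
            for k in range(length):
                src = second[min(k, len(second) - 1)]
                seg.append(_renumber(src, number + k, "A", off))
            pending_strand = None
            residues.extend(seg)
            number += length
            continue
        else:
            seg = extended_chain(length, start=number)
        off = region_offset()
        for r in seg:
            for a in r.atoms:
                a.coords = a.coords + off
            r.chain_id = "A"
        residues.extend(seg)
        number += length

    if pending_strand is not None:  # unpaired strand reads as coil
        s0, l0 = pending_strand
        seg = extended_chain(l0, start=s0)
        off = region_offset()
        for r in seg:
            for a in r.atoms:
                a.coords = a.coords + off
            r.chain_id = "A"
        residues.extend(seg)

    residues.sort(key=lambda r: r.number)
    for i, r in enumerate(residues):
        r.name = names[i % len(names)]
    return residues_to_model(residues, source_id=f"structured_pocket(seed={spec.seed})")


def _renumber(src: Residue, number: int, chain_id: str, offset: np.ndarray) -> Residue:
    atoms = [Atom(serial=a.serial, name=a.name, element=a.element,
                  coords=a.coords + offset) for a in src.atoms]
    return Residue(name=src.name, number=number, chain_id=chain_id, atoms=atoms)


def spec_to_pdb(spec: SyntheticSpec) -> str:
    """Convenience: build the toy complex and render it as PDB text."""
    return write_pdb(toy_complex(spec))
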