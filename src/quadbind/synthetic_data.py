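"""Synthetic structures and scripted trajectories with known ground truth.

Everything the analysis pipeline consumes can be generated here: an idealized
three-tetrad 22-mer G-quadruplex (d(AGGGTTAGGGTTAGGGTTAGGG)) with two channel
K+ ions, a B-form d([GC]10)2 duplex, a planar tricyclic ligand with three
substituent arms and a +3 net charge, and rigid-body binding trajectories
scripted through unbound / approach / top / bottom / groove states with
optional base-flip events.

The structures are geometric emulations, not force-field models: bases are
placed from the standard planar reference-frame coordinates, guanine tetrads
are arranged so the Hoogsteen hydrogen-bond network (N1-H1...O6 and
N2-H2...N7 around the cycle) is detected under the 3.5 Å / 120° criteria, and
a deoxyribose/phosphate backbone with canonical-B-like torsions is attached to
every base.  Partial charges, Lennard-Jones and Born parameters are plausible
synthetic magnitudes keyed by (residue, atom) name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .structio import (
    AtomRecord,
    Frame,
    StructureModel,
    StructureError,
    Trajectory,
    build_exclusions,
    write_annotations,
    write_multimodel_pdb,
    write_parameter_table,
)

__all__ = [
    "QuadruplexSpec",
    "TrajectoryScript",
    "build_quadruplex",
    "build_duplex",
    "build_ligand",
    "assemble_complex",
    "generate_trajectory",
    "parameter_rows",
    "write_dataset",
]


# ---------------------------------------------------------------------------
# element-level nonbonded parameters (AMBER-magnitude synthetic defaults)
# (lj_rmin_half Å, lj_epsilon kcal/mol, gb_radius Å, gb_scale)
# ---------------------------------------------------------------------------
ELEMENT_PARAMS = {
    "H": (1.10, 0.0157, 1.20, 0.85),
    "C": (1.45, 0.0860, 1.70, 0.72),
    "N": (1.40, 0.1700, 1.55, 0.79),
    "O": (1.35, 0.2100, 1.50, 0.85),
    "P": (1.60, 0.2000, 1.85, 0.86),
    "K": (1.45, 0.1937, 1.95, 0.80),
}
GB_RADIUS_H_ON_N = 1.30  # mBondi-style: H bonded to N gets a larger radius


# ---------------------------------------------------------------------------
# standard planar base coordinates (x, y in the base reference frame, z = 0)
# ---------------------------------------------------------------------------
BASE_COORDS: dict[str, dict[str, tuple[float, float]]] = {
    "DG": {
        "C1'": (-2.477, 5.399), "N9": (-1.289, 4.551), "C8": (0.023, 4.962),
        "N7": (0.870, 3.969), "C5": (0.071, 2.833), "C6": (0.424, 1.460),
        "O6": (1.554, 0.955), "N1": (-0.700, 0.641), "C2": (-1.999, 1.087),
        "N2": (-2.949, 0.139), "N3": (-2.342, 2.364), "C4": (-1.265, 3.177),
    },
    "DA": {
        "C1'": (-2.479, 5.346), "N9": (-1.291, 4.498), "C8": (0.024, 4.897),
        "N7": (0.877, 3.902), "C5": (0.071, 2.771), "C6": (0.369, 1.398),
        "N6": (1.611, 0.909), "N1": (-0.668, 0.532), "C2": (-1.912, 1.023),
        "N3": (-2.320, 2.290), "C4": (-1.267, 3.124),
    },
    "DC": {
        "C1'": (-2.477, 5.402), "N1": (-1.285, 4.542), "C2": (-1.472, 3.158),
        "O2": (-2.628, 2.709), "N3": (-0.391, 2.344), "C4": (0.837, 2.868),
        "N4": (1.875, 2.027), "C5": (1.056, 4.275), "C6": (-0.023, 5.068),
    },
    "DT": {
        "C1'": (-2.481, 5.354), "N1": (-1.284, 4.500), "C2": (-1.462, 3.135),
        "O2": (-2.562, 2.608), "N3": (-0.298, 2.407), "C4": (0.994, 2.897),
        "O4": (1.944, 2.119), "C5": (1.106, 4.338), "C7": (2.466, 4.961),
        "C6": (-0.024, 5.057),
    },
}

BASE_BONDS: dict[str, list[tuple[str, str]]] = {
    "DG": [("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"), ("C6", "O6"),
           ("C6", "N1"), ("N1", "C2"), ("C2", "N2"), ("C2", "N3"), ("N3", "C4"),
           ("C4", "C5"), ("C4", "N9")],
    "DA": [("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"), ("C6", "N6"),
           ("C6", "N1"), ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"),
           ("C4", "N9")],
    "DC": [("N1", "C2"), ("C2", "O2"), ("C2", "N3"), ("N3", "C4"), ("C4", "N4"),
           ("C4", "C5"), ("C5", "C6"), ("C6", "N1")],
    "DT": [("N1", "C2"), ("C2", "O2"), ("C2", "N3"), ("N3", "C4"), ("C4", "O4"),
           ("C4", "C5"), ("C5", "C7"), ("C5", "C6"), ("C6", "N1")],
}

# hydrogens: name -> (parent, reference neighbours, bond length)
# one neighbour: amine pair placed in-plane at +-120 deg from the parent bond;
# two neighbours: H along the external bisector.
BASE_HYDROGENS: dict[str, list[tuple[str, str, tuple[str, ...], float]]] = {
    "DG": [("H1", "N1", ("C2", "C6"), 1.01), ("H21", "N2", ("C2",), 1.01),
           ("H22", "N2", ("C2",), 1.01), ("H8", "C8", ("N7", "N9"), 1.08)],
    "DA": [("H61", "N6", ("C6",), 1.01), ("H62", "N6", ("C6",), 1.01),
           ("H2", "C2", ("N1", "N3"), 1.08), ("H8", "C8", ("N7", "N9"), 1.08)],
    "DC": [("H41", "N4", ("C4",), 1.01), ("H42", "N4", ("C4",), 1.01),
           ("H5", "C5", ("C4", "C6"), 1.08), ("H6", "C6", ("C5", "N1"), 1.08)],
    "DT": [("H3", "N3", ("C2", "C4"), 1.01), ("H6", "C6", ("C5", "N1"), 1.08)],
}

GLYCOSIDIC = {"DG": ("N9", "C4", "C8"), "DA": ("N9", "C4", "C8"),
              "DC": ("N1", "C2", "C6"), "DT": ("N1", "C2", "C6")}

# per-(residue, atom) synthetic partial charges; atoms absent default to 0
BACKBONE_CHARGES = {
    "P": 1.17, "OP1": -0.78, "OP2": -0.78, "O5'": -0.50, "C5'": 0.00,
    "C4'": 0.10, "O4'": -0.37, "C3'": 0.10, "O3'": -0.52, "C2'": -0.09,
    "C1'": 0.10,
}
BASE_CHARGES: dict[str, dict[str, float]] = {
    "DG": {"N9": 0.05, "C8": 0.14, "H8": 0.16, "N7": -0.57, "C5": 0.18,
           "C6": 0.48, "O6": -0.56, "N1": -0.51, "H1": 0.35, "C2": 0.74,
           "N2": -0.94, "H21": 0.43, "H22": 0.43, "N3": -0.66, "C4": 0.18},
    "DC": {"N1": -0.02, "C2": 0.68, "O2": -0.65, "N3": -0.77, "C4": 0.84,
           "N4": -0.97, "H41": 0.44, "H42": 0.44, "C5": -0.52, "H5": 0.19,
           "C6": 0.00, "H6": 0.23},
    "DT": {"N1": -0.02, "C2": 0.57, "O2": -0.59, "N3": -0.43, "H3": 0.34,
           "C4": 0.52, "O4": -0.56, "C5": 0.00, "C7": -0.23, "C6": -0.22,
           "H6": 0.26},
    "DA": {"N9": 0.05, "C8": 0.16, "H8": 0.19, "N7": -0.61, "C5": 0.07,
           "C6": 0.70, "N6": -0.90, "H61": 0.41, "H62": 0.41, "N1": -0.76,
           "C2": 0.57, "H2": 0.07, "N3": -0.70, "C4": 0.38},
}


def _rz(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([[math.cos(t), -math.sin(t), 0.0],
                     [math.sin(t), math.cos(t), 0.0],
                     [0.0, 0.0, 1.0]])


def _nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D bonded to C with given C-D bond, B-C-D angle, A-B-C-D torsion."""
    a, b, c = np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        bond * math.sin(theta) * math.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _base_atoms(resname: str) -> dict[str, np.ndarray]:
    """Base heavy atoms (without C1') plus hydrogens in the standard frame."""
    coords = {k: np.array([x, y, 0.0]) for k, (x, y) in BASE_COORDS[resname].items()}
    out = {k: v for k, v in coords.items() if k != "C1'"}
    for hname, parent, refs, blen in BASE_HYDROGENS[resname]:
        p = coords[parent]
        if len(refs) == 2:
            d = -(
                (coords[refs[0]] - p) / np.linalg.norm(coords[refs[0]] - p)
                + (coords[refs[1]] - p) / np.linalg.norm(coords[refs[1]] - p)
            )
            d /= np.linalg.norm(d)
            out[hname] = p + blen * d
        else:
            # amine H pair in-plane at +-120 deg from the parent->ref bond
            ref_dir = (coords[refs[0]] - p) / np.linalg.norm(coords[refs[0]] - p)
            sign = 1.0 if hname.endswith("1") or hname in ("H41", "H61") else -1.0
            rot = _rz(sign * 120.0)
            out[hname] = p + blen * (rot @ ref_dir)
    return out


# canonical-B-like torsion targets used to attach the sugar/phosphate
CHI_ANTI = -102.0
GAMMA_B = 38.0
BETA_B = 136.0
DELTA_B = 140.0
NU1 = 34.2   # O4'-C1'-C2'-C3' (C2'-endo pucker)
NU2 = -34.2  # C1'-C2'-C3'-C4'


@lru_cache(maxsize=8)
def _sugar_template(resname: str) -> tuple[tuple[tuple[str, float, float, float], ...], tuple[tuple[str, str], ...]]:
    """Sugar + phosphate atoms in the base standard frame, built by internal
    coordinates so that chi, gamma, beta, delta take canonical-B-like values."""
    base = {k: np.array([x, y, 0.0]) for k, (x, y) in BASE_COORDS[resname].items()}
    ngly, canchor, _ = GLYCOSIDIC[resname]
    c1p = base["C1'"]
    n = base[ngly]
    c_ref = base[canchor]
    pos: dict[str, np.ndarray] = {"C1'": c1p}
    pos["O4'"] = _nerf(c_ref, n, c1p, 1.42, 108.2, CHI_ANTI)
    pos["C2'"] = _nerf(c_ref, n, c1p, 1.52, 113.8, CHI_ANTI - 119.0)
    pos["C3'"] = _nerf(pos["O4'"], c1p, pos["C2'"], 1.53, 102.5, NU1)
    pos["C4'"] = _nerf(c1p, pos["C2'"], pos["C3'"], 1.52, 102.8, NU2)
    pos["C5'"] = _nerf(pos["C2'"], pos["C3'"], pos["C4'"], 1.51, 114.7, -118.0)
    pos["O3'"] = _nerf(pos["C5'"], pos["C4'"], pos["C3'"], 1.42, 110.0, DELTA_B)
    pos["O5'"] = _nerf(pos["C3'"], pos["C4'"], pos["C5'"], 1.44, 110.2, GAMMA_B)
    pos["P"] = _nerf(pos["C4'"], pos["C5'"], pos["O5'"], 1.59, 120.9, BETA_B)
    pos["OP1"] = _nerf(pos["C5'"], pos["O5'"], pos["P"], 1.48, 108.0, 75.0)
    pos["OP2"] = _nerf(pos["C5'"], pos["O5'"], pos["P"], 1.48, 108.0, -165.0)
    bonds = (
        ("P", "OP1"), ("P", "OP2"), ("P", "O5'"), ("O5'", "C5'"),
        ("C5'", "C4'"), ("C4'", "O4'"), ("C4'", "C3'"), ("C3'", "O3'"),
        ("C3'", "C2'"), ("C2'", "C1'"), ("C1'", "O4'"), ("C1'", ngly),
    )
    atoms = tuple(
        (name, float(v[0]), float(v[1]), float(v[2]))
        for name, v in pos.items()
    )
    return atoms, bonds


def _residue_atoms(resname: str, five_prime: bool = False,
                   mirror_sugar: bool = False):
    """All atoms of one nucleotide in the base standard frame.

    Returns (list of (name, element, xyz), list of intra-residue bond name
    pairs).  ``mirror_sugar`` reflects the sugar/phosphate through the base
    plane, which reverses the direction the backbone propagates (used for
    reversed-polarity strands).
    """
    atoms: list[tuple[str, str, np.ndarray]] = []
    for name, xyz in _base_atoms(resname).items():
        atoms.append((name, name[0], xyz))
    sugar, sbonds = _sugar_template(resname)
    skip = {"P", "OP1", "OP2"} if five_prime else set()
    for name, x, y, z in sugar:
        if name in skip:
            continue
        zz = -z if mirror_sugar else z
        atoms.append((name, name[0], np.array([x, y, zz])))
    bonds = list(BASE_BONDS[resname])
    for hname, parent, _, _ in BASE_HYDROGENS[resname]:
        bonds.append((parent, hname))
    for b in sbonds:
        if b[0] in skip or b[1] in skip:
            continue
        bonds.append(b)
    return atoms, bonds


# ---------------------------------------------------------------------------
# tetrad in-plane placement
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _tetrad_placement() -> tuple[float, float]:
    """Radial offset d and in-plane rotation phi placing four guanines in a
    Hoogsteen-compatible cycle: N1(i)..O6(i+1) and N2(i)..N7(i+1) near 2.9 Å,
    with N2(i)..O6(i+1) pushed beyond the H-bond cutoff so each tetrad yields
    exactly eight detected bonds."""
    g = _base_atoms("DG")
    heavy = [k for k in g if not k.startswith("H")]
    hb_pairs = {("N1", "O6"), ("N2", "N7")}

    def _angle(p_d, p_h, p_a) -> float:
        v1 = p_d - p_h
        v2 = p_a - p_h
        c = float(v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    def residuals(params):
        d, phi = params
        rot = _rz(math.degrees(phi))
        shift = np.array([d, 0.0, 0.0])
        a = {k: rot @ v + shift for k, v in g.items()}
        r90 = _rz(90.0)
        b = {k: r90 @ v for k, v in a.items()}
        res = [
            np.linalg.norm(a["N1"] - b["O6"]) - 2.90,
            np.linalg.norm(a["N2"] - b["N7"]) - 2.90,
        ]
        # donor-H-acceptor angles comfortably above the 120 deg cutoff
        res.append(0.05 * max(0.0, 150.0 - _angle(a["N1"], a["H1"], b["O6"])))
        hn2 = min(("H21", "H22"),
                  key=lambda h: np.linalg.norm(a[h] - b["N7"]))
        res.append(0.05 * max(0.0, 150.0 - _angle(a["N2"], a[hn2], b["N7"])))
        # keep the amine-to-carbonyl separation off the 3.5 Å cutoff
        res.append(2.0 * max(0.0, 3.8 - np.linalg.norm(a["N2"] - b["O6"])))
        # steric floor between adjacent and opposite guanines
        for ka in heavy:
            for kb in heavy:
                if (ka, kb) in hb_pairs:
                    continue
                res.append(2.0 * max(0.0, 2.9 - np.linalg.norm(a[ka] - b[kb])))
        r180 = _rz(180.0)
        c = {k: r180 @ v for k, v in a.items()}
        for ka in heavy:
            for kb in heavy:
                res.append(2.0 * max(0.0, 3.0 - np.linalg.norm(a[ka] - c[kb])))
        return res

    best = None
    for phi0 in np.linspace(0.0, 2 * math.pi, 13)[:-1]:
        for d0 in (3.0, 4.0, 5.0):
            sol = least_squares(residuals, x0=[d0, phi0], method="trf",
                                bounds=([2.0, -10.0], [8.0, 10.0]))
            if best is None or sol.cost < best.cost:
                best = sol
    d, phi = best.x
    return float(d), float(phi)


def _guanine_frame(strand: int, tetrad: int, rise: float, twist: float):
    """Rigid placement (R, t) for the guanine of strand s in tetrad t."""
    d, phi = _tetrad_placement()
    rot = _rz(twist * tetrad + 90.0 * strand) @ _rz(math.degrees(phi))
    shift = _rz(twist * tetrad + 90.0 * strand) @ np.array([d, 0.0, 0.0])
    shift = shift + np.array([0.0, 0.0, rise * tetrad])
    return rot, shift


# ---------------------------------------------------------------------------
# model assembly helpers
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self):
        self.atoms: list[AtomRecord] = []
        self.coords: list[np.ndarray] = []
        self.bonds: list[tuple[int, int]] = []

    def add_residue(self, resname: str, residue_index: int, chain: str,
                    placed: list[tuple[str, str, np.ndarray]],
                    bond_names: list[tuple[str, str]],
                    charges: dict[str, float]) -> dict[str, int]:
        name_to_idx: dict[str, int] = {}
        for name, element, xyz in placed:
            idx = len(self.atoms)
            rmh, eps, gbr, gbs = ELEMENT_PARAMS[element]
            self.atoms.append(AtomRecord(
                index=idx, name=name, element=element,
                residue_index=residue_index, residue_name=resname,
                chain_id=chain, charge=charges.get(name, 0.0),
                lj_rmin_half=rmh, lj_epsilon=eps, gb_radius=gbr, gb_scale=gbs,
            ))
            self.coords.append(np.asarray(xyz, float))
            name_to_idx[name] = idx
        for a, b in bond_names:
            if a in name_to_idx and b in name_to_idx:
                self.bonds.append((name_to_idx[a], name_to_idx[b]))
        return name_to_idx

    def fix_h_on_n_radii(self) -> None:
        # polar hydrogens: larger intrinsic Born radius (mBondi convention),
        # small LJ radius so hydrogen-bonded contacts are not steric clashes
        adj: dict[int, list[int]] = {}
        for i, j in self.bonds:
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
        for a in self.atoms:
            if a.element == "H" and any(
                self.atoms[n].element == "N" for n in adj.get(a.index, [])
            ):
                a.gb_radius = GB_RADIUS_H_ON_N
                a.lj_rmin_half = 0.6

    def finish(self, roles: dict[str, set[int]], **annot) -> tuple[StructureModel, Frame]:
        model = StructureModel(atoms=self.atoms, bonds=self.bonds, roles=roles,
                               **annot)
        self.fix_h_on_n_radii()
        build_exclusions(model)
        model.validate()
        return model, Frame(np.array(self.coords), time=0.0)


def _nucleotide_charges(resname: str, five_prime: bool) -> dict[str, float]:
    q = dict(BACKBONE_CHARGES)
    if five_prime:
        for k in ("P", "OP1", "OP2"):
            q.pop(k)
    q.update(BASE_CHARGES[resname])
    return q


# ---------------------------------------------------------------------------
# quadruplex
# ---------------------------------------------------------------------------

SEQUENCE_22MER = "AGGGTTAGGGTTAGGGTTAGGG"
STRAND_DIRECTIONS = {
    "parallel": (1, 1, 1, 1),
    "antiparallel": (1, -1, 1, -1),
    "hybrid": (1, 1, -1, 1),
}


@dataclass
class QuadruplexSpec:
    """Geometry of the emulated intramolecular G-quadruplex."""

    n_tetrads: int = 3
    rise: float = 3.4          # Å between tetrad planes
    tetrad_twist: float = 30.0  # deg between stacked tetrads
    topology: str = "parallel"
    sequence: str = SEQUENCE_22MER

    def __post_init__(self) -> None:
        if self.n_tetrads < 2:
            raise StructureError("need at least 2 tetrads")
        if self.topology not in STRAND_DIRECTIONS:
            raise StructureError(f"unknown topology {self.topology!r}")


def build_quadruplex(spec: QuadruplexSpec | None = None) -> tuple[StructureModel, Frame]:
    """Idealized three-tetrad quadruplex with channel ions and TTA loops.

    Guanine runs of the 22-mer occupy the tetrads (tetrad 1 nearest the 5'
    terminus); loop and terminal residues are placed on arcs just outside the
    G-core so they are available for base-flip scripting.
    """
    spec = spec or QuadruplexSpec()
    seq = spec.sequence
    nt = spec.n_tetrads
    g_runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "G":
            j = i
            while j < len(seq) and seq[j] == "G":
                j += 1
            g_runs.append(list(range(i, j)))
            i = j
        else:
            i += 1
    if len(g_runs) != 4 or any(len(r) != nt for r in g_runs):
        raise StructureError("sequence must contain four G-runs of n_tetrads each")
    dirs = STRAND_DIRECTIONS[spec.topology]

    # residue -> (strand, tetrad) for guanines
    g_place: dict[int, tuple[int, int]] = {}
    tetrads: list[list[int]] = [[] for _ in range(nt)]
    for s, run in enumerate(g_runs):
        order = range(nt) if dirs[s] > 0 else range(nt - 1, -1, -1)
        for k, t in enumerate(order):
            g_place[run[k]] = (s, t)
            tetrads[t].append(run[k])

    b = _Builder()
    loop_targets: dict[int, np.ndarray] = {}
    # outer radius of the G-core (guanine nucleotides incl. backbone):
    # loops sit just outside it, inside the base-flip detection annulus
    g_atoms, _ = _residue_atoms("DG")
    rot0, shift0 = _guanine_frame(0, 0, spec.rise, spec.tetrad_twist)
    placed_g = np.array([rot0 @ x + shift0 for n, e, x in g_atoms if e != "H"])
    core_radius = float(np.max(np.linalg.norm(placed_g[:, :2], axis=1)))

    for res, letter in enumerate(seq):
        resname = "D" + letter
        five_prime = res == 0
        atoms, bonds = _residue_atoms(resname, five_prime=five_prime)
        if res in g_place:
            s, t = g_place[res]
            mirror = dirs[s] < 0
            if mirror:
                atoms, bonds = _residue_atoms(resname, five_prime=five_prime,
                                              mirror_sugar=True)
            rot, shift = _guanine_frame(s, t, spec.rise, spec.tetrad_twist)
            placed = [(n, e, rot @ x + shift) for n, e, x in atoms]
        else:
            # loop / terminal residue: initial slot in an inter-strand gap at
            # mid-height; final position set by clash-relaxation below
            run_idx = sum(1 for r in g_runs if r[-1] < res)
            within = (res - 1) % 6  # position inside the TTA loop
            if res == 0:
                ang, zoff = 300.0, spec.rise * (nt - 1) / 2.0
            else:
                ang = 90.0 * run_idx - 30.0 + 25.0 * (within - 4)
                zoff = (1.2, spec.rise * (nt - 1) / 2.0, 5.6)[within - 3]
            rad = core_radius + 1.0
            centroid = np.array([
                np.mean([v[0] for v in BASE_COORDS[resname].values()]),
                np.mean([v[1] for v in BASE_COORDS[resname].values()]), 0.0,
            ])
            # orient the sugar/phosphate tail radially outward
            tail = dict((n, x) for n, _, x in atoms)
            tail_pt = tail.get("P", tail["C4'"])
            tail_ang = math.degrees(math.atan2(tail_pt[1] - centroid[1],
                                               tail_pt[0] - centroid[0]))
            rot = _rz(ang - tail_ang)
            target = np.array([
                rad * math.cos(math.radians(ang)),
                rad * math.sin(math.radians(ang)), zoff,
            ])
            shift = target - rot @ centroid
            placed = [(n, e, rot @ x + shift) for n, e, x in atoms]
            loop_targets[res] = target
        b.add_residue(resname, res, "A", placed, bonds,
                      _nucleotide_charges(resname, five_prime))

    # backbone links along the chain
    for res in range(len(seq) - 1):
        i = next(a.index for a in b.atoms
                 if a.residue_index == res and a.name == "O3'")
        j = next(a.index for a in b.atoms
                 if a.residue_index == res + 1 and a.name == "P")
        b.bonds.append((i, j))

    # channel ions between adjacent tetrad planes, on the axis
    ion_indices = []
    n_res = len(seq)
    for k in range(nt - 1):
        idx = len(b.atoms)
        rmh, eps, gbr, gbs = ELEMENT_PARAMS["K"]
        b.atoms.append(AtomRecord(
            index=idx, name="K+", element="K", residue_index=n_res + k,
            residue_name="K", chain_id="I", charge=1.0,
            lj_rmin_half=rmh, lj_epsilon=eps, gb_radius=gbr, gb_scale=gbs,
        ))
        b.coords.append(np.array([0.0, 0.0, spec.rise * (k + 0.5)]))
        ion_indices.append(idx)

    _relax_residues(b, loop_targets,
                    r_bounds=(core_radius + 0.3, core_radius + 1.2),
                    z_bounds=(0.6, spec.rise * (nt - 1) - 0.6))

    dna_atoms = {a.index for a in b.atoms if a.residue_name != "K"}
    roles = {"receptor": dna_atoms, "ion": set(ion_indices)}
    return b.finish(roles, tetrads=tetrads, channel_ions=ion_indices,
                    topology_label=spec.topology)


BASE_RING_FOR_FLIPS = ("N1", "C2", "N3", "C4", "C5", "C6", "O6", "N7", "C8",
                       "N9", "O2", "N4", "O4", "N6", "N2", "C7")


def _relax_residues(b: _Builder, targets: dict[int, np.ndarray],
                    r_bounds: tuple[float, float],
                    z_bounds: tuple[float, float],
                    clash_floor: float = 2.7, passes: int = 2) -> None:
    """Deterministic rigid-body relaxation of loop/terminal residues.

    Each movable residue is rotated/translated to remove non-bonded clashes
    against the (fixed) G-core and the other residues, with soft walls keeping
    its base-ring centroid inside an annulus around the core (so flips stay
    detectable) and a weak spring to its initial slot.  Bonded pairs within
    three bonds are exempt from the clash penalty.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    coords = np.array(b.coords)
    n = len(b.atoms)
    # graph-distance <= 3 exemptions
    tmp = StructureModel(atoms=b.atoms, bonds=b.bonds)
    build_exclusions(tmp)
    exempt = tmp.excluded_pairs | tmp.pairs14

    res_atoms = {res: np.array([a.index for a in b.atoms
                                if a.residue_index == res])
                 for res in targets}
    ring_sel = {res: np.array([a.index for a in b.atoms
                               if a.residue_index == res
                               and a.name in BASE_RING_FOR_FLIPS])
                for res in targets}

    for _ in range(passes):
        for res in sorted(targets):
            idx = res_atoms[res]
            other = np.setdiff1d(np.arange(n), idx)
            # prefilter: other atoms within 16 Å of the residue centroid
            cen = coords[idx].mean(axis=0)
            near = other[np.linalg.norm(coords[other] - cen, axis=1) < 16.0]
            pair_ok = np.ones((idx.size, near.size), dtype=bool)
            for i, ai in enumerate(idx):
                for j, aj in enumerate(near):
                    if frozenset((int(ai), int(aj))) in exempt:
                        pair_ok[i, j] = False
            ring_local = coords[ring_sel[res]] - cen
            local = coords[idx] - cen
            xo = coords[near]

            def cost(p):
                rot = Rotation.from_rotvec(p[3:]).as_matrix()
                moved = local @ rot.T + cen + p[:3]
                d = np.linalg.norm(moved[:, None, :] - xo[None, :, :], axis=2)
                clash = np.where(pair_ok, np.maximum(0.0, clash_floor - d), 0.0)
                ring = ring_local @ rot.T + cen + p[:3]
                rc = ring.mean(axis=0)
                rr = math.hypot(rc[0], rc[1])
                wall = (max(0.0, r_bounds[0] - rr) ** 2
                        + max(0.0, rr - r_bounds[1]) ** 2
                        + max(0.0, z_bounds[0] - rc[2]) ** 2
                        + max(0.0, rc[2] - z_bounds[1]) ** 2)
                spring = float(np.sum((rc - targets[res]) ** 2))
                return float(np.sum(clash ** 2)) + 5.0 * wall + 0.02 * spring

            sol = minimize(cost, np.zeros(6), method="Powell",
                           options={"maxiter": 4000, "xtol": 1e-3})
            rot = Rotation.from_rotvec(sol.x[3:]).as_matrix()
            coords[idx] = local @ rot.T + cen + sol.x[:3]
    for i in range(n):
        b.coords[i] = coords[i]


# ---------------------------------------------------------------------------
# duplex
# ---------------------------------------------------------------------------

DUPLEX_RISE = 3.38
DUPLEX_TWIST = 36.0
_FLIP_X = np.diag([1.0, -1.0, -1.0])  # proper rotation pairing the WC partner


def build_duplex(n_bp: int = 20) -> tuple[StructureModel, Frame]:
    """Idealized B-form d([GC]n)2 duplex (rise 3.38 Å, twist 36 deg/bp).

    Chain A runs 5'->3' up the helix axis; chain B is generated base-pair by
    base-pair with the standard-frame Watson-Crick flip, so every G.C pair
    presents the three canonical hydrogen bonds.  The terminal base pairs are
    annotated as pseudo-tetrads (first pair nearest chain A's 5' end).
    """
    if n_bp < 2:
        raise StructureError("need at least 2 base pairs")
    b = _Builder()
    # chain A residues 0..n_bp-1 (5'->3'), chain B residues n_bp..2n_bp-1
    # (5'->3', pairing chain A in reverse)
    for i in range(n_bp):
        resname = "DG" if i % 2 == 0 else "DC"
        rot = _rz(DUPLEX_TWIST * i)
        shift = np.array([0.0, 0.0, DUPLEX_RISE * i])
        atoms, bonds = _residue_atoms(resname, five_prime=(i == 0))
        placed = [(n, e, rot @ x + shift) for n, e, x in atoms]
        b.add_residue(resname, i, "A", placed, bonds,
                      _nucleotide_charges(resname, i == 0))
    for j in range(n_bp):
        res = n_bp + j
        bp = n_bp - 1 - j  # chain B residue j pairs base pair bp
        partner = "DG" if bp % 2 == 0 else "DC"
        resname = "DC" if partner == "DG" else "DG"
        rot = _rz(DUPLEX_TWIST * bp) @ _FLIP_X
        shift = np.array([0.0, 0.0, DUPLEX_RISE * bp])
        atoms, bonds = _residue_atoms(resname, five_prime=(j == 0))
        placed = [(n, e, rot @ x + shift) for n, e, x in atoms]
        b.add_residue(resname, res, "B", placed, bonds,
                      _nucleotide_charges(resname, j == 0))
    for chain_start, chain_len in ((0, n_bp), (n_bp, n_bp)):
        for r in range(chain_start, chain_start + chain_len - 1):
            i = next(a.index for a in b.atoms
                     if a.residue_index == r and a.name == "O3'")
            j = next(a.index for a in b.atoms
                     if a.residue_index == r + 1 and a.name == "P")
            b.bonds.append((i, j))
    roles = {"receptor": {a.index for a in b.atoms}}
    pseudo = [[0, 2 * n_bp - 1], [n_bp - 1, n_bp]]
    return b.finish(roles, tetrads=pseudo, channel_ions=[],
                    topology_label="duplex")


# ---------------------------------------------------------------------------
# ligand
# ---------------------------------------------------------------------------

AROMATIC_BOND = 1.40


def build_ligand() -> tuple[StructureModel, Frame]:
    """Planar tricyclic ligand: fused three-ring core with one ring nitrogen,
    an anilino-like arm and two cationic side chains; net charge +3."""
    a = AROMATIC_BOND
    centers = [np.array([k * a * math.sqrt(3.0), 0.0, 0.0]) for k in range(3)]
    verts: list[np.ndarray] = []
    for c in centers:
        for k in range(6):
            ang = math.radians(30.0 + 60.0 * k)
            v = c + a * np.array([math.cos(ang), math.sin(ang), 0.0])
            if not any(np.linalg.norm(v - w) < 1e-6 for w in verts):
                verts.append(v)
    mid_x = centers[1][0]
    core: list[tuple[str, str, np.ndarray]] = []
    n10_pos = c9_pos = None
    ci = 0
    for v in verts:
        if abs(v[0] - mid_x) < 1e-6 and v[1] < -1.0:
            core.append(("N10", "N", v))
            n10_pos = v
        elif abs(v[0] - mid_x) < 1e-6 and v[1] > 1.0:
            ci += 1
            core.append((f"C{ci}", "C", v))
            c9_pos = v
        else:
            ci += 1
            core.append((f"C{ci}", "C", v))
    c9_name = next(n for n, _, v in core if v is c9_pos)

    atoms = list(core)
    bonds: list[tuple[str, str]] = []
    names = [n for n, _, _ in core]
    pos = {n: v for n, _, v in core}
    for i, ni in enumerate(names):
        for nj in names[i + 1:]:
            if np.linalg.norm(pos[ni] - pos[nj]) < a + 0.05:
                bonds.append((ni, nj))
    degree: dict[str, int] = {n: 0 for n in names}
    for x, y in bonds:
        degree[x] += 1
        degree[y] += 1

    # arm attachment carbons: outer-ring vertices pointing away along -x/+x
    left = min((n for n in names if degree[n] == 2 and n != "N10"),
               key=lambda n: (pos[n][0], pos[n][1]))
    right = max((n for n in names if degree[n] == 2 and n != "N10"),
                key=lambda n: (pos[n][0], -pos[n][1]))

    charges: dict[str, float] = {}
    # protonated ring nitrogen (+1 spread over N10/H10 and its neighbours)
    n10_neighbors = [x if y == "N10" else y for x, y in bonds if "N10" in (x, y)]
    atoms.append(("H10", "H", pos["N10"] + np.array([0.0, -1.01, 0.0])))
    bonds.append(("N10", "H10"))
    charges["N10"] = -0.10
    charges["H10"] = 0.45
    for nb in n10_neighbors:
        charges[nb] = charges.get(nb, 0.0) + 0.65 / len(n10_neighbors)

    # anilino-like arm on the central top carbon
    n15 = pos[c9_name] + np.array([0.0, AROMATIC_BOND, 0.0])
    atoms.append(("N15", "N", n15))
    bonds.append((c9_name, "N15"))
    atoms.append(("H15", "H", n15 + np.array([-1.01, 0.0, 0.0])))
    bonds.append(("N15", "H15"))
    charges["N15"] = -0.30
    charges["H15"] = 0.30
    ph_center = n15 + np.array([0.0, AROMATIC_BOND + 1.39, 0.0])
    ph_names = []
    for k in range(6):
        ang = math.radians(-90.0 + 60.0 * k)
        v = ph_center + 1.39 * np.array([math.cos(ang), math.sin(ang), 0.0])
        nm = f"C{15 + k + 1}"
        ph_names.append(nm)
        atoms.append((nm, "C", v))
    for k in range(6):
        bonds.append((ph_names[k], ph_names[(k + 1) % 6]))
    bonds.append(("N15", ph_names[0]))
    phpos = {n: v for n, _, v in atoms if n in ph_names}
    for nm in ph_names[1:]:
        v = phpos[nm]
        d = v - ph_center
        d /= np.linalg.norm(d)
        hn = "H" + nm[1:]
        atoms.append((hn, "H", v + 1.08 * d))
        bonds.append((nm, hn))
        charges[nm] = -0.115
        charges[hn] = 0.115

    # two cationic side arms (3 carbons + terminal N, +1 each), extended
    # radially outward from the core in the ring plane
    core_centroid = np.mean([pos[n] for n in names], axis=0)
    for tag, attach in (("1", left), ("2", right)):
        prev = attach
        base = pos[attach]
        d = base - core_centroid
        d[2] = 0.0
        d /= np.linalg.norm(d)
        perp = np.array([-d[1], d[0], 0.0])
        chain = []
        for k, cn in enumerate(("CA", "CB", "CC")):
            nm = cn + tag
            v = base + 1.30 * (k + 1) * d + 0.55 * ((k + 1) % 2) * perp
            atoms.append((nm, "C", v))
            bonds.append((prev, nm))
            prev = nm
            chain.append(v)
        nd = "ND" + tag
        v = chain[-1] + 1.30 * d + 0.55 * perp
        atoms.append((nd, "N", v))
        bonds.append((prev, nd))
        charges[nd] = 0.30
        for hk, off in (("1", 0.6 * d + 0.85 * perp),
                        ("2", 0.95 * d - 0.40 * perp)):
            hn = f"HD{tag}{hk}"
            atoms.append((hn, "H", v + off))
            bonds.append((nd, hn))
            charges[hn] = 0.35

    # in-plane hydrogens on remaining core CH carbons, along the external
    # bisector of the ring neighbours
    neighbors: dict[str, list[str]] = {n: [] for n in names}
    for a_, b_ in bonds:
        if a_ in neighbors and b_ in neighbors:
            neighbors[a_].append(b_)
            neighbors[b_].append(a_)
    substituted = {c9_name, left, right, "N10"}
    for n in names:
        if degree[n] == 2 and n not in substituted:
            nb = neighbors[n][:2]
            d = -sum((pos[m] - pos[n]) / np.linalg.norm(pos[m] - pos[n])
                     for m in nb)
            d /= np.linalg.norm(d)
            hn = "H" + n[1:] + "C"
            atoms.append((hn, "H", pos[n] + 1.08 * d))
            bonds.append((n, hn))
            charges[n] = -0.115
            charges[hn] = 0.115

    b = _Builder()
    idx = b.add_residue("LIG", 0, "L", atoms, bonds, charges)
    roles = {"ligand": {a.index for a in b.atoms}}
    model, frame = b.finish(roles)
    model.ligand_core = sorted(idx[n] for n in names)
    total = sum(a.charge for a in model.atoms)
    assert abs(total - 3.0) < 1e-9, f"ligand net charge {total}"
    return model, frame


# ---------------------------------------------------------------------------
# complex assembly
# ---------------------------------------------------------------------------

def assemble_complex(
    receptor: tuple[StructureModel, Frame],
    ligand: tuple[StructureModel, Frame],
) -> tuple[StructureModel, Frame]:
    """Concatenate a receptor system (with ions) and a ligand into one model."""
    rm, rf = receptor
    lm, lf = ligand
    off = rm.n_atoms
    atoms = [AtomRecord(**vars(a)) for a in rm.atoms]
    max_res = max(a.residue_index for a in rm.atoms) + 1
    for a in lm.atoms:
        d = dict(vars(a))
        d["index"] = a.index + off
        d["residue_index"] = a.residue_index + max_res
        atoms.append(AtomRecord(**d))
    bonds = list(rm.bonds) + [(i + off, j + off) for i, j in lm.bonds]
    roles = {k: set(v) for k, v in rm.roles.items()}
    roles.setdefault("ligand", set()).update(i + off for i in range(lm.n_atoms))
    model = StructureModel(
        atoms=atoms, bonds=bonds, roles=roles,
        tetrads=[list(t) for t in rm.tetrads],
        channel_ions=list(rm.channel_ions),
        ligand_core=[i + off for i in lm.ligand_core],
        topology_label=rm.topology_label,
    )
    build_exclusions(model)
    model.validate()
    coords = np.vstack([rf.coordinates, lf.coordinates])
    return model, Frame(coords, time=0.0)


# ---------------------------------------------------------------------------
# scripted trajectories
# ---------------------------------------------------------------------------

LIGAND_STATES = ("unbound", "approach", "top", "bottom", "groove")


@dataclass
class TrajectoryScript:
    """Ordered (n_frames, ligand state, noise amplitude Å) segments plus
    base-flip events (residue, flip-out frame, flip-in frame or None)."""

    segments: list[tuple[int, str, float]]
    flips: list[tuple[int, int, int | None]] = field(default_factory=list)
    seed: int = 0
    dt: float = 50.0  # ps between frames
    flip_displacement: float = 6.0  # Å radial
    flip_ramp: int = 10  # frames

    def __post_init__(self) -> None:
        for n, state, noise in self.segments:
            if state not in LIGAND_STATES:
                raise StructureError(f"unknown ligand state {state!r}")
            if n <= 0 or noise < 0:
                raise StructureError("segment frames must be > 0, noise >= 0")

    @property
    def n_frames(self) -> int:
        return sum(n for n, _, _ in self.segments)

    def labels(self) -> list[str]:
        out: list[str] = []
        for n, state, _ in self.segments:
            out.extend([state] * n)
        return out

    def noise_amplitudes(self) -> np.ndarray:
        out: list[float] = []
        for n, _, noise in self.segments:
            out.extend([noise] * n)
        return np.array(out)


def _stack_axis(model: StructureModel, coords: np.ndarray):
    """(unit axis, tetrad-1 centroid, tetrad-last centroid) from annotations."""
    ring_names = ("N1", "C2", "N3", "C4", "C5", "C6", "O6", "N7", "C8", "N9",
                  "O2", "N4", "O4", "C7")
    cents = []
    for tet in (model.tetrads[0], model.tetrads[-1]):
        idx = [a.index for a in model.atoms
               if a.residue_index in tet and a.name in ring_names]
        cents.append(coords[idx].mean(axis=0))
    axis = cents[1] - cents[0]
    axis = axis / np.linalg.norm(axis)
    return axis, cents[0], cents[1]


def _slide_to_contact(receptor_xyz: np.ndarray, lig_xyz: np.ndarray,
                      direction: np.ndarray,
                      receptor_heavy: np.ndarray, ligand_heavy: np.ndarray,
                      start: float = 12.0,
                      min_contacts: int = 20, cutoff: float = 3.0,
                      min_sep: float = 2.2, min_sep_heavy: float = 2.6,
                      step: float = 0.05) -> np.ndarray:
    """Slide the ligand along -direction from ``start`` Å out until the
    atom-contact count reaches ``min_contacts`` or a separation floor is hit
    (heavy-heavy pairs keep ``min_sep_heavy``, any pair ``min_sep``; hydrogen
    contacts may come closer, as in hydrogen-bonded interfaces).  Returns the
    chosen ligand coordinates."""
    from scipy.spatial import cKDTree

    tree = cKDTree(receptor_xyz)
    tree_heavy = cKDTree(receptor_xyz[receptor_heavy])
    direction = direction / np.linalg.norm(direction)
    offset = start
    best = lig_xyz + direction * offset
    while offset > -start:
        cand = lig_xyz + direction * offset
        dmin, _ = tree.query(cand, k=1)
        dmin_h, _ = tree_heavy.query(cand[ligand_heavy], k=1)
        if dmin.min() < min_sep or dmin_h.min() < min_sep_heavy:
            break
        best = cand
        pairs = tree.query_ball_point(cand, cutoff)
        n_contacts = sum(len(p) for p in pairs)
        if n_contacts >= min_contacts:
            break
        offset -= step
    return best


def _pose_coords(state: str, receptor: tuple[StructureModel, Frame],
                 ligand: tuple[StructureModel, Frame]) -> np.ndarray:
    """Rigid ligand placement for a scripted binding state."""
    rm, rf = receptor
    lm, lf = ligand
    axis, c1, c3 = _stack_axis(rm, rf.coordinates)
    core = lf.coordinates[lm.ligand_core]
    core_cen = core.mean(axis=0)
    lig0 = lf.coordinates - core_cen  # core-centred, plane is z=0 already
    rec_heavy_mask = np.array([a.element != "H" for a in rm.atoms])
    lig_heavy_mask = np.array([a.element != "H" for a in lm.atoms])
    if state == "top":
        anchor = c1
        outward = -axis
    elif state == "bottom":
        anchor = c3
        outward = axis
    elif state == "groove":
        heavy = rm.heavy_indices(rm.roles.get("receptor"))
        xyz = rf.coordinates[heavy]
        mid = 0.5 * (c1 + c3)
        # approach face-on against the groove surface (plane normal along the
        # radial, long axis tangential), then settle by rigid-body LJ docking
        # constrained to hug the G-core flank
        radial = np.array([1.0, 0.0, 0.0])
        radial -= axis * (radial @ axis)
        radial /= np.linalg.norm(radial)
        rot = np.column_stack([np.cross(axis, radial), axis, radial])
        lig = lig0 @ rot.T
        max_r = np.max(np.abs((xyz - mid) @ radial))
        placed = lig + mid + radial * (max_r + 8.0)
        start = _slide_to_contact(rf.coordinates, placed, radial,
                                  rec_heavy_mask, lig_heavy_mask)
        core_sel = [i for i, h in enumerate(lig_heavy_mask)
                    if h and i in set(lm.ligand_core)]
        tet_res = {r for t in rm.tetrads for r in t}
        tet_idx = [a.index for a in rm.atoms
                   if a.residue_index in tet_res and a.element != "H"]
        rel = rf.coordinates[tet_idx] - c1
        core_rmax = float(np.max(np.linalg.norm(
            rel - np.outer(rel @ axis, axis), axis=1)))
        span = float((c3 - c1) @ axis)

        def walls(pose):
            cen = pose[core_sel].mean(axis=0) - c1
            s = float(cen @ axis)
            rr = float(np.linalg.norm(cen - s * axis))
            return (max(0.0, rr - (core_rmax + 3.2)) ** 2
                    + max(0.0, 0.5 - s) ** 2
                    + max(0.0, s - (span - 0.5)) ** 2)

        return _dock_ligand(rf.coordinates, rm, lm, start, walls)
    else:
        raise StructureError(f"no pose defined for state {state!r}")
    # stacked poses: ligand plane parallel to the tetrad planes, settled by
    # rigid-body LJ docking constrained to stay past the terminal plane
    rot = _rotation_from_to(np.array([0.0, 0.0, 1.0]), outward)
    lig = lig0 @ rot.T + anchor + outward * 8.0
    start = _slide_to_contact(rf.coordinates, lig, outward,
                              rec_heavy_mask, lig_heavy_mask)
    core_sel = [i for i, h in enumerate(lig_heavy_mask)
                if h and i in set(lm.ligand_core)]
    span = float(np.linalg.norm(c3 - c1))
    u = (c3 - c1) / span

    def walls(pose):
        cen = pose[core_sel].mean(axis=0) - c1
        s = float(cen @ u)
        rr = float(np.linalg.norm(cen - s * u))
        if state == "top":
            axial = max(0.0, s + 1.2) ** 2
        else:
            axial = max(0.0, (span + 1.2) - s) ** 2
        return axial + max(0.0, rr - 4.0) ** 2

    return _dock_ligand(rf.coordinates, rm, lm, start, walls)


def _dock_ligand(receptor_xyz: np.ndarray, rm: StructureModel,
                 lm: StructureModel, start: np.ndarray, walls,
                 wall_weight: float = 100.0) -> np.ndarray:
    """Rigid-body pose refinement: minimize the receptor-ligand LJ energy
    (6 degrees of freedom) plus soft wall penalties; deterministic."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    rh_r = np.array([a.lj_rmin_half for a in rm.atoms])
    ep_r = np.array([a.lj_epsilon for a in rm.atoms])
    rh_l = np.array([a.lj_rmin_half for a in lm.atoms])
    ep_l = np.array([a.lj_epsilon for a in lm.atoms])
    rmin = rh_l[:, None] + rh_r[None, :]
    eps = np.sqrt(np.outer(ep_l, ep_r))
    cen0 = start.mean(axis=0)
    local = start - cen0

    def cost(p):
        rot = Rotation.from_rotvec(p[3:]).as_matrix()
        pose = local @ rot.T + cen0 + p[:3]
        d = np.linalg.norm(pose[:, None, :] - receptor_xyz[None, :, :], axis=2)
        x6 = np.where(d < 9.0, (rmin / np.maximum(d, 0.5)) ** 6, 0.0)
        e = float(np.sum(eps * (x6 * x6 - 2.0 * x6)))
        return e + wall_weight * walls(pose)

    sol = minimize(cost, np.zeros(6), method="Powell",
                   options={"maxiter": 3000, "xtol": 1e-3})
    rot = Rotation.from_rotvec(sol.x[3:]).as_matrix()
    return local @ rot.T + cen0 + sol.x[:3]


def _rotation_from_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal proper rotation taking unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 deg: rotate about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def generate_trajectory(
    receptor: tuple[StructureModel, Frame],
    ligand: tuple[StructureModel, Frame],
    script: TrajectoryScript,
) -> tuple[Trajectory, pd.DataFrame, list[tuple[int, int, int | None]]]:
    """Scripted rigid-body binding trajectory with per-frame truth labels.

    Returns (complex trajectory, truth table with columns frame/time_ps/state,
    flip ground-truth intervals).  Deterministic for a fixed script seed.
    """
    rm, rf = receptor
    lm, lf = ligand
    model, frame0 = assemble_complex(receptor, ligand)
    n_rec = rm.n_atoms
    rng = np.random.default_rng(script.seed)

    labels = script.labels()
    noises = script.noise_amplitudes()
    n_frames = script.n_frames

    # precompute pose coordinates for each state used
    pose_cache: dict[str, np.ndarray] = {}
    for state in {s for s in labels if s in ("top", "bottom", "groove")}:
        pose_cache[state] = _pose_coords(state, receptor, ligand)

    axis, c1, c3 = _stack_axis(rm, rf.coordinates)
    rec_heavy = rm.heavy_indices(rm.roles.get("receptor"))
    dna_center = rf.coordinates[rec_heavy].mean(axis=0)

    # unbound position: 30 Å beyond the first bound pose, collinear with the
    # DNA centre so the centre-to-centre distance decreases monotonically
    # during the approach
    first_pose = next((s for s in labels if s in pose_cache), None)
    if first_pose is None:
        far_dir = axis.copy()
        far_pos = lf.coordinates - lf.coordinates[lm.ligand_core].mean(axis=0) \
            + dna_center + far_dir * 40.0
        pose_for_unbound = far_pos
    else:
        pose = pose_cache[first_pose]
        d = pose[lm.ligand_core].mean(axis=0) - dna_center
        pose_for_unbound = pose + d / np.linalg.norm(d) * 30.0

    # flip bookkeeping
    flip_targets: dict[int, np.ndarray] = {}
    ring_names = set().union(*(set(BASE_COORDS[k]) for k in BASE_COORDS)) - {"C1'"}
    base_atom_idx: dict[int, np.ndarray] = {}
    for res, f_out, f_in in script.flips:
        idx = np.array([a.index for a in rm.atoms
                        if a.residue_index == res
                        and (a.name in ring_names or a.name.startswith("H"))],
                       dtype=int)
        if idx.size == 0:
            raise StructureError(f"flip script references unknown residue {res}")
        base_atom_idx[res] = idx
        cen = rf.coordinates[idx].mean(axis=0)
        radial = cen - c1 - axis * ((cen - c1) @ axis)
        nr = np.linalg.norm(radial)
        flip_targets[res] = radial / nr if nr > 1e-9 else np.array([1.0, 0, 0])

    def flip_amount(res_events, frame: int) -> float:
        # ramps lie inside the (flip-out, flip-in) interval so the detected
        # threshold crossings bracket the scripted event frames
        res, f_out, f_in = res_events
        ramp = script.flip_ramp
        if frame < f_out:
            return 0.0
        if frame < f_out + ramp:
            return (frame - f_out + 1) / ramp
        if f_in is None or frame < f_in - ramp:
            return 1.0
        if frame < f_in:
            return (f_in - frame) / ramp
        return 0.0

    # per-segment ligand positions
    frames: list[Frame] = []
    records = []
    seg_bounds = np.cumsum([0] + [n for n, _, _ in script.segments])
    for k in range(n_frames):
        state = labels[k]
        if state == "unbound":
            lig_xyz = pose_for_unbound
        elif state == "approach":
            seg = next(i for i in range(len(script.segments))
                       if seg_bounds[i] <= k < seg_bounds[i + 1])
            nxt = labels[seg_bounds[seg + 1]] if seg + 1 < len(script.segments) else None
            target = pose_cache.get(nxt, pose_for_unbound)
            frac = (k - seg_bounds[seg] + 1) / (seg_bounds[seg + 1] - seg_bounds[seg])
            lig_xyz = (1 - frac) * pose_for_unbound + frac * target
        else:
            lig_xyz = pose_cache[state]
        xyz = np.vstack([rf.coordinates, lig_xyz])
        for ev in script.flips:
            amt = flip_amount(ev, k)
            if amt > 0:
                idx = base_atom_idx[ev[0]]
                xyz = xyz.copy()
                xyz[idx] += flip_targets[ev[0]] * (amt * script.flip_displacement)
        if noises[k] > 0:
            xyz = xyz + rng.normal(0.0, noises[k], size=xyz.shape)
        frames.append(Frame(xyz, time=script.dt * k))
        records.append((k, script.dt * k, state))

    traj = Trajectory(model=model, frames=frames)
    truth = pd.DataFrame(records, columns=["frame", "time_ps", "state"])
    return traj, truth, list(script.flips)


# ---------------------------------------------------------------------------
# dataset output
# ---------------------------------------------------------------------------

def parameter_rows(model: StructureModel) -> list[tuple]:
    """Unique (residue, atom) parameter rows covering every atom of the model."""
    seen = {}
    for a in model.atoms:
        key = (a.residue_name, a.name)
        row = (a.residue_name, a.name, a.charge, a.lj_rmin_half,
               a.lj_epsilon, a.gb_radius, a.gb_scale)
        if key in seen and seen[key] != row:
            raise StructureError(f"inconsistent parameters for {key}")
        seen[key] = row
    return list(seen.values())


def write_dataset(prefix, traj: Trajectory,
                  truth: pd.DataFrame | None = None) -> dict[str, str]:
    """Write frames.pdb / params.txt / annot.yaml (and truth.tsv) for a run."""
    import os

    paths = {
        "frames": f"{prefix}_frames.pdb",
        "params": f"{prefix}_params.txt",
        "annot": f"{prefix}_annot.yaml",
    }
    os.makedirs(os.path.dirname(os.path.abspath(paths["frames"])), exist_ok=True)
    write_multimodel_pdb(paths["frames"], traj)
    write_parameter_table(paths["params"], parameter_rows(traj.model))
    write_annotations(paths["annot"], traj.model)
    if truth is not None:
        paths["truth"] = f"{prefix}_truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
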