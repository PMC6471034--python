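"""Binding-pathway order parameters, backbone torsions and base-flip calls.

Five per-frame observables characterise a binding trajectory: hydrogen-bond
counts per annotated G-tetrad (3.5 Å donor-acceptor / 120° donor-H-acceptor
criteria), the angle between the ligand ring plane and the nearest tetrad
plane, receptor backbone RMSD versus the initial structure, ligand RMSD versus
the first frame after a receptor-backbone fit, the receptor-to-ligand
centre-to-centre distance R, and the channel K+-K+ distance.

Backbone torsions follow the standard nucleic-acid definitions::

    alpha  O3'(i-1)-P-O5'-C5'      delta  C5'-C4'-C3'-O3'
    beta   P-O5'-C5'-C4'           eps    C4'-C3'-O3'-P(i+1)
    gamma  O5'-C5'-C4'-C3'         zeta   C3'-O3'-P(i+1)-O5'(i+1)
    chi    O4'-C1'-N9-C4 (purines) / O4'-C1'-N1-C2 (pyrimidines)

Base flips are called from the radial displacement of the base-ring centroid
off the tetrad stack axis, smoothed with a five-frame majority filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import dihedral_angle, fit_plane, interplane_angle, rmsd_after_fit
from .structio import Frame, StructureModel, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "HBOND_DIST_CUTOFF",
    "HBOND_ANGLE_CUTOFF",
    "hydrogen_bonds",
    "default_donors_acceptors",
    "tetrad_hbond_count",
    "center_to_center",
    "ion_ion_distance",
    "order_parameter_series",
    "backbone_torsions",
    "torsion_histogram",
    "detect_base_flips",
    "TorsionProfile",
]

HBOND_DIST_CUTOFF = 3.5    # Å, donor to acceptor
HBOND_ANGLE_CUTOFF = 120.0  # deg, donor-H-acceptor

# donor (heavy, hydrogen) and acceptor atom names per residue type
DONOR_TEMPLATES: dict[str, list[tuple[str, str]]] = {
    "DG": [("N1", "H1"), ("N2", "H21"), ("N2", "H22")],
    "DC": [("N4", "H41"), ("N4", "H42")],
    "DT": [("N3", "H3")],
    "DA": [("N6", "H61"), ("N6", "H62")],
    "LIG": [("N10", "H10"), ("N15", "H15"),
            ("ND1", "HD11"), ("ND1", "HD12"),
            ("ND2", "HD21"), ("ND2", "HD22")],
}
ACCEPTOR_TEMPLATES: dict[str, list[str]] = {
    "DG": ["O6", "N7", "N3"],
    "DC": ["O2", "N3"],
    "DT": ["O2", "O4"],
    "DA": ["N1", "N3", "N7"],
    "LIG": ["N10"],
}
# Hoogsteen subset used for tetrad counting
GUANINE_TETRAD_DONORS = [("N1", "H1"), ("N2", "H21"), ("N2", "H22")]
GUANINE_TETRAD_ACCEPTORS = ["O6", "N7"]

GUANINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "O6", "N7", "C8", "N9")
BASE_RING_NAMES = ("N1", "C2", "N3", "C4", "C5", "C6", "O6", "N7", "C8", "N9",
                   "O2", "N4", "O4", "N6", "N2", "C7")


def hydrogen_bonds(
    frame: Frame,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    dist_cutoff: float = HBOND_DIST_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
) -> list[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triples meeting both criteria:
    dist(D, A) <= 3.5 Å and the D-H-A angle >= 120°."""
    if not donors or not acceptors:
        return []
    xyz = frame.coordinates
    d_idx = np.array([d for d, _ in donors], dtype=int)
    h_idx = np.array([h for _, h in donors], dtype=int)
    a_idx = np.asarray(acceptors, dtype=int)
    # guard against mispaired (D, H) atoms; generous bound so thermal noise
    # on a genuine covalent pair does not trip it
    dh = np.linalg.norm(xyz[d_idx] - xyz[h_idx], axis=1)
    if np.any(dh > 3.0):
        bad = int(d_idx[np.argmax(dh)])
        raise ValueError(f"donor atom {bad} is not bonded to its hydrogen")
    d_xyz = xyz[d_idx][:, None, :]   # (nd, 1, 3)
    h_xyz = xyz[h_idx][:, None, :]
    a_xyz = xyz[a_idx][None, :, :]   # (1, na, 3)
    dist = np.linalg.norm(d_xyz - a_xyz, axis=2)
    v1 = d_xyz - h_xyz
    v2 = a_xyz - h_xyz
    cosang = np.sum(v1 * v2, axis=2) / (
        np.linalg.norm(v1, axis=2) * np.maximum(np.linalg.norm(v2, axis=2), 1e-12)
    )
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    out: list[tuple[int, int, int]] = []
    rows, cols = np.nonzero((dist <= dist_cutoff) & (ang >= angle_cutoff))
    for r, c in zip(rows, cols):
        if int(d_idx[r]) == int(a_idx[c]):
            continue
        out.append((int(d_idx[r]), int(h_idx[r]), int(a_idx[c])))
    return out


def default_donors_acceptors(
    model: StructureModel, residues: list[int] | None = None
) -> tuple[list[tuple[int, int]], list[int]]:
    """Donor (D, H) pairs and acceptor atoms assigned from residue templates."""
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    pool = set(residues) if residues is not None else None
    by_res: dict[int, dict[str, int]] = {}
    res_name: dict[int, str] = {}
    for a in model.atoms:
        if pool is not None and a.residue_index not in pool:
            continue
        by_res.setdefault(a.residue_index, {})[a.name] = a.index
        res_name[a.residue_index] = a.residue_name
    for res, names in by_res.items():
        rn = res_name[res]
        for d, h in DONOR_TEMPLATES.get(rn, []):
            if d in names and h in names:
                donors.append((names[d], names[h]))
        for acc in ACCEPTOR_TEMPLATES.get(rn, []):
            if acc in names:
                acceptors.append(names[acc])
    return donors, acceptors


def tetrad_hbond_count(frame: Frame, model: StructureModel,
                       tetrad: list[int]) -> int:
    """Inter-guanine Hoogsteen hydrogen bonds within one annotated tetrad
    (donors N1-H1 / N2-H2x, acceptors O6 / N7)."""
    by_res: dict[int, dict[str, int]] = {}
    for a in model.atoms:
        if a.residue_index in tetrad:
            if a.residue_name not in ("DG", "G"):
                raise ValueError(
                    f"residue {a.residue_index} in tetrad is {a.residue_name},"
                    " not guanine"
                )
            by_res.setdefault(a.residue_index, {})[a.name] = a.index
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    res_of: dict[int, int] = {}
    for res, names in by_res.items():
        for d, h in GUANINE_TETRAD_DONORS:
            if d in names and h in names:
                donors.append((names[d], names[h]))
                res_of[names[d]] = res
        for acc in GUANINE_TETRAD_ACCEPTORS:
            if acc in names:
                acceptors.append(names[acc])
                res_of[names[acc]] = res
    bonds = hydrogen_bonds(frame, donors, acceptors)
    return sum(1 for d, _, a in bonds if res_of[d] != res_of[a])


def center_to_center(frame: Frame, group_a, group_b) -> float:
    """Distance between the unweighted centroids of two atom groups."""
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("centre-to-centre groups must be nonempty")
    ca = frame.coordinates[group_a].mean(axis=0)
    cb = frame.coordinates[group_b].mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def ion_ion_distance(frame: Frame, channel_ions) -> float:
    ions = list(channel_ions)
    if len(ions) != 2:
        raise ValueError(f"expected exactly 2 channel ions, got {len(ions)}")
    return float(np.linalg.norm(
        frame.coordinates[ions[0]] - frame.coordinates[ions[1]]
    ))


def _tetrad_ring_indices(model: StructureModel, tetrad: list[int]) -> list[int]:
    return [a.index for a in model.atoms
            if a.residue_index in tetrad and a.name in BASE_RING_NAMES]


def order_parameter_series(traj: Trajectory) -> pd.DataFrame:
    """The five per-frame binding observables as a tidy table.

    Columns: frame, time_ps, hb_t1..hb_tN, angle_deg (ligand plane vs nearest
    tetrad plane), rmsd_receptor (backbone vs frame 0), rmsd_ligand (vs frame
    0 after receptor fit), R (centre-to-centre), dKK (NaN without two channel
    ions).
    """
    model = traj.model
    backbone = model.backbone_indices()
    lig = model.role_indices("ligand")
    lig_heavy = model.heavy_indices(lig)
    rec_heavy = model.heavy_indices(model.roles.get("receptor"))
    core = model.heavy_indices(model.ligand_core or lig)
    tet_ring = [_tetrad_ring_indices(model, t) for t in model.tetrads]
    ref = traj.frames[0].coordinates
    rows = []
    for k, fr in enumerate(traj.frames):
        xyz = fr.coordinates
        row: dict[str, float] = {"frame": k, "time_ps": fr.time}
        for t, tet in enumerate(model.tetrads, start=1):
            row[f"hb_t{t}"] = tetrad_hbond_count(fr, model, tet)
        if core.size and tet_ring:
            lig_norm, lig_cen = fit_plane(xyz[core])
            best = min(
                tet_ring,
                key=lambda idx: np.linalg.norm(xyz[idx].mean(axis=0) - lig_cen),
            )
            tet_norm, _ = fit_plane(xyz[best])
            row["angle_deg"] = interplane_angle(lig_norm, tet_norm)
        else:
            row["angle_deg"] = np.nan
        row["rmsd_receptor"] = rmsd_after_fit(xyz, ref, backbone, backbone)
        row["rmsd_ligand"] = (
            rmsd_after_fit(xyz, ref, backbone, lig) if lig.size else np.nan
        )
        row["R"] = (
            center_to_center(fr, rec_heavy, lig_heavy) if lig_heavy.size else np.nan
        )
        row["dKK"] = (
            ion_ion_distance(fr, model.channel_ions)
            if len(model.channel_ions) == 2 else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


TORSION_ATOMS = {
    "alpha": (("O3'", -1), ("P", 0), ("O5'", 0), ("C5'", 0)),
    "beta": (("P", 0), ("O5'", 0), ("C5'", 0), ("C4'", 0)),
    "gamma": (("O5'", 0), ("C5'", 0), ("C4'", 0), ("C3'", 0)),
    "delta": (("C5'", 0), ("C4'", 0), ("C3'", 0), ("O3'", 0)),
    "eps": (("C4'", 0), ("C3'", 0), ("O3'", 0), ("P", 1)),
    "zeta": (("C3'", 0), ("O3'", 0), ("P", 1), ("O5'", 1)),
}
PURINES = ("DG", "DA", "G", "A")


@dataclass
class TorsionProfile:
    """Backbone/glycosidic torsions for one residue over a trajectory."""

    residue: int
    table: pd.DataFrame  # columns: frame, alpha..zeta, chi (NaN = undefined)


def backbone_torsions(traj: Trajectory, residue: int) -> TorsionProfile:
    """alpha..zeta and chi for one residue, every frame; angles that need a
    neighbouring residue outside the chain are marked missing (NaN)."""
    model = traj.model
    names: dict[tuple[int, str], int] = {
        (a.residue_index, a.name): a.index for a in model.atoms
    }
    chain = {a.residue_index: a.chain_id for a in model.atoms}
    resname = next(a.residue_name for a in model.atoms
                   if a.residue_index == residue)

    def atom(res: int, name: str) -> int | None:
        if res != residue and chain.get(res) != chain.get(residue):
            return None
        return names.get((res, name))

    quads: dict[str, list[int] | None] = {}
    for angle, spec in TORSION_ATOMS.items():
        idx = [atom(residue + off, nm) for nm, off in spec]
        quads[angle] = idx if all(i is not None for i in idx) else None
        if quads[angle] is None:
            logger.warning("torsion %s undefined for residue %d", angle, residue)
    if resname in PURINES:
        chi_names = ("O4'", "C1'", "N9", "C4")
    else:
        chi_names = ("O4'", "C1'", "N1", "C2")
    idx = [atom(residue, nm) for nm in chi_names]
    quads["chi"] = idx if all(i is not None for i in idx) else None

    rows = []
    for k, fr in enumerate(traj.frames):
        xyz = fr.coordinates
        row: dict[str, float] = {"frame": k}
        for angle, q in quads.items():
            row[angle] = (
                dihedral_angle(*(xyz[i] for i in q)) if q is not None else np.nan
            )
        rows.append(row)
    return TorsionProfile(residue=residue, table=pd.DataFrame(rows))


def torsion_histogram(profile: TorsionProfile, bin_width: float = 10.0,
                      window: slice | None = None) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-angle histograms over (-180, 180], optionally over a trailing
    frame window (e.g. the last fifth of the trajectory)."""
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    table = profile.table if window is None else profile.table.iloc[window]
    out = {}
    for angle in list(TORSION_ATOMS) + ["chi"]:
        vals = table[angle].dropna().to_numpy()
        counts, _ = np.histogram(vals, bins=edges)
        out[angle] = (counts, edges)
    return out


def detect_base_flips(
    traj: Trajectory, residue: int,
    threshold: float | None = None,
    pad: float = 2.0,
    smooth: int = 5,
) -> tuple[list[tuple[int, int | None]], np.ndarray]:
    """Flip intervals for one residue from radial base displacement.

    The per-frame flip state is ``radial distance of the base-ring centroid
    from the tetrad stack axis > threshold`` (default: the groove radius --
    the frame-0 maximum radial extent of the tetrad nucleotides' heavy atoms
    -- plus ``pad`` Å), smoothed by a ``smooth``-frame majority filter.
    Returns (intervals as (flip-out, flip-in or None), smoothed per-frame
    states).
    """
    model = traj.model
    if not model.tetrads:
        raise ValueError("flip detection requires tetrad annotations")
    ring_idx = [a.index for a in model.atoms
                if a.residue_index == residue and a.name in BASE_RING_NAMES]
    if not ring_idx:
        raise ValueError(f"residue {residue} has no base ring atoms")
    t_first = _tetrad_ring_indices(model, model.tetrads[0])
    t_last = _tetrad_ring_indices(model, model.tetrads[-1])
    tet_res = {r for t in model.tetrads for r in t}
    all_tet = [a.index for a in model.atoms
               if a.residue_index in tet_res and a.element != "H"]

    def axis_of(xyz):
        c1 = xyz[t_first].mean(axis=0)
        c3 = xyz[t_last].mean(axis=0)
        ax = c3 - c1
        return c1, ax / np.linalg.norm(ax)

    if threshold is None:
        xyz0 = traj.frames[0].coordinates
        c1, ax = axis_of(xyz0)
        rel = xyz0[all_tet] - c1
        radial = np.linalg.norm(rel - np.outer(rel @ ax, ax), axis=1)
        threshold = float(radial.max()) + pad

    raw = np.zeros(len(traj), dtype=bool)
    for k, fr in enumerate(traj.frames):
        xyz = fr.coordinates
        c1, ax = axis_of(xyz)
        cen = xyz[ring_idx].mean(axis=0) - c1
        r = float(np.linalg.norm(cen - (cen @ ax) * ax))
        raw[k] = r > threshold
    # centred majority filter
    half = smooth // 2
    states = np.zeros_like(raw)
    for k in range(len(raw)):
        win = raw[max(0, k - half): k + half + 1]
        states[k] = win.sum() * 2 > win.size
    intervals: list[tuple[int, int | None]] = []
    prev = False
    start = None
    for k, s in enumerate(states):
        if s and not prev:
            start = k
        elif prev and not s:
            intervals.append((start, k))
            start = None
        prev = s
    if start is not None:
        intervals.append((start, None))
    return intervals, states
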