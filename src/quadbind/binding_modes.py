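"""Stable-complex detection, pose clustering and binding-mode classification.

A frame is a *stable complex* when the receptor and ligand share more than 10
atom contacts at a 3.0 Å atom-to-atom cutoff.  Stable poses are clustered with
the Daura algorithm on the pairwise ligand RMSD (computed after superposing
every frame onto the first frame by the receptor backbone, with no further
ligand fit) at a 2 Å cutoff; families below 1% of the stable population are
dropped, and the survivors are merged into top / bottom / groove binding modes
by a geometric rule on the centroid pose (the ligand-core centroid relative to
the terminal tetrad planes and the axial cylinder).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform, pdist

from .geometry import kabsch_superpose
from .structio import Frame, StructureModel, Trajectory

__all__ = [
    "ContactSeries",
    "ClusterFamily",
    "BindingModeResult",
    "atom_contacts",
    "stable_complex_mask",
    "pairwise_ligand_rmsd_matrix",
    "daura_cluster",
    "filter_population",
    "classify_mode",
    "analyze_binding_modes",
    "CONTACT_CUTOFF",
    "STABLE_MIN_CONTACTS",
    "CLUSTER_CUTOFF",
    "MIN_POPULATION",
]

CONTACT_CUTOFF = 3.0        # Å, atom-to-atom
STABLE_MIN_CONTACTS = 11    # stable ⇔ contacts > 10, i.e. >= 11
CLUSTER_CUTOFF = 2.0        # Å, pairwise ligand RMSD
MIN_POPULATION = 0.01       # fraction of stable frames

TETRAD_RING_NAMES = ("N1", "C2", "N3", "C4", "C5", "C6", "O6", "N7", "C8",
                     "N9", "O2", "N4", "O4")


@dataclass
class ContactSeries:
    """Per-frame receptor-ligand contact counts and the stability flags."""

    counts: np.ndarray          # (n_frames,) int
    stable: np.ndarray          # (n_frames,) bool; stable ⇔ counts > 10

    @property
    def stable_frames(self) -> np.ndarray:
        return np.flatnonzero(self.stable)


@dataclass
class ClusterFamily:
    """One Daura cluster: members, its centroid and the population fraction."""

    members: np.ndarray          # original frame indices
    centroid: int                # original frame index; member with most neighbours
    population: float            # fraction of stable frames
    mode: str = ""               # top / bottom / groove / unbound


@dataclass
class BindingModeResult:
    families: list[ClusterFamily] = field(default_factory=list)
    mode_populations: dict[str, float] = field(default_factory=dict)
    contact_series: ContactSeries | None = None
    n_stable: int = 0


def atom_contacts(frame: Frame, group_a, group_b,
                  cutoff: float = CONTACT_CUTOFF) -> int:
    """Number of (a, b) atom pairs within ``cutoff`` Å."""
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("contact groups must be disjoint")
    if group_a.size == 0 or group_b.size == 0:
        return 0
    xa = frame.coordinates[group_a]
    xb = frame.coordinates[group_b]
    tree = cKDTree(xb)
    return int(sum(len(p) for p in tree.query_ball_point(xa, cutoff)))


def stable_complex_mask(traj: Trajectory, cutoff: float = CONTACT_CUTOFF,
                        min_contacts: int = STABLE_MIN_CONTACTS) -> ContactSeries:
    """Per-frame contact counts; a frame is stable iff contacts >= min_contacts
    (the default 11 encodes the strict 'greater than 10' rule)."""
    model = traj.model
    rec = model.role_indices("receptor")
    lig = model.role_indices("ligand")
    if rec.size == 0 or lig.size == 0:
        raise ValueError("model roles must define receptor and ligand groups")
    counts = np.array([
        atom_contacts(fr, rec, lig, cutoff) for fr in traj.frames
    ])
    return ContactSeries(counts=counts, stable=counts >= min_contacts)


def pairwise_ligand_rmsd_matrix(
    traj: Trajectory, stable: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise ligand RMSD over the selected frames, no ligand fit.

    Every frame is first superposed onto frame 0 of the trajectory by the
    receptor backbone; matrix entry (i, j) is then the plain ligand-atom RMSD
    between aligned frames.  Returns (matrix, original frame indices); both
    empty when no frame is selected.
    """
    model = traj.model
    sel = (np.flatnonzero(np.asarray(stable, dtype=bool))
           if stable is not None else np.arange(len(traj)))
    if sel.size == 0:
        return np.zeros((0, 0)), sel
    backbone = model.backbone_indices()
    lig = model.role_indices("ligand")
    ref = traj.frames[0].coordinates
    aligned = np.empty((sel.size, lig.size, 3))
    for k, fi in enumerate(sel):
        tf, _ = kabsch_superpose(traj.frames[fi].coordinates, ref, backbone)
        aligned[k] = tf.apply(traj.frames[fi].coordinates)[lig]
    flat = aligned.reshape(sel.size, -1)
    # RMSD_ij = ||flat_i - flat_j|| / sqrt(n_lig)
    mat = squareform(pdist(flat)) / np.sqrt(lig.size)
    return mat, sel


def daura_cluster(matrix: np.ndarray, cutoff: float = CLUSTER_CUTOFF,
                  frame_indices: np.ndarray | None = None) -> list[ClusterFamily]:
    """Greedy neighbour clustering (Daura): repeatedly take the frame with the
    most neighbours within ``cutoff`` as a centroid and remove its cluster.

    Ties in neighbour count are broken by the lowest frame index.  Families
    are returned ordered by descending population (fraction of the clustered
    frames); equal populations order by centroid index.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size and np.isnan(matrix).any():
        raise ValueError("NaN in RMSD matrix")
    n = matrix.shape[0]
    if n == 0:
        return []
    if matrix.shape != (n, n):
        raise ValueError("matrix must be square")
    frame_indices = (np.asarray(frame_indices, dtype=int)
                     if frame_indices is not None else np.arange(n))
    nb = matrix <= cutoff
    np.fill_diagonal(nb, True)
    active = np.ones(n, dtype=bool)
    families: list[ClusterFamily] = []
    while active.any():
        counts = (nb & active).sum(axis=1)
        counts[~active] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(nb[center] & active)
        active[members] = False
        families.append(ClusterFamily(
            members=frame_indices[members],
            centroid=int(frame_indices[center]),
            population=members.size / n,
        ))
    families.sort(key=lambda f: (-f.population, f.centroid))
    return families


def filter_population(families: list[ClusterFamily],
                      threshold: float = MIN_POPULATION) -> list[ClusterFamily]:
    """Drop families below the population threshold (boundary inclusive);
    survivors keep their original populations, with no renormalisation."""
    return [f for f in families if f.population >= threshold]


def _tetrad_plane_points(model: StructureModel, coords: np.ndarray,
                         tetrad: list[int]) -> np.ndarray:
    idx = [a.index for a in model.atoms
           if a.residue_index in tetrad and a.name in TETRAD_RING_NAMES]
    return coords[idx]


def classify_mode(frame: Frame, model: StructureModel,
                  cylinder_pad: float = 3.0, groove_dist: float = 6.0) -> str:
    """Geometric binding-mode label for one pose: top / bottom / groove.

    The ligand-core centroid is projected onto the tetrad stack axis (tetrad 1,
    nearest 5', to the last tetrad).  Beyond the tetrad-1 plane inside the
    axial cylinder -> ``top``; beyond the last tetrad plane -> ``bottom``;
    otherwise within ``groove_dist`` of the receptor surface -> ``groove``.
    A pose with no receptor contact is labelled ``unbound``.
    """
    if not model.tetrads:
        raise ValueError("classification requires tetrad annotations")
    core = model.ligand_core or sorted(model.roles.get("ligand", set()))
    core = model.heavy_indices(core)
    coords = frame.coordinates
    rec = model.role_indices("receptor")
    lig = model.role_indices("ligand")
    if atom_contacts(frame, rec, lig) == 0:
        return "unbound"
    p1 = _tetrad_plane_points(model, coords, model.tetrads[0])
    p3 = _tetrad_plane_points(model, coords, model.tetrads[-1])
    c1 = p1.mean(axis=0)
    c3 = p3.mean(axis=0)
    axis = c3 - c1
    span = float(np.linalg.norm(axis))
    axis /= span
    radius = max(
        float(np.max(np.linalg.norm(p1 - c1 - np.outer((p1 - c1) @ axis, axis), axis=1))),
        float(np.max(np.linalg.norm(p3 - c3 - np.outer((p3 - c3) @ axis, axis), axis=1))),
    ) + cylinder_pad
    cen = coords[core].mean(axis=0)
    s = float((cen - c1) @ axis)
    radial = float(np.linalg.norm(cen - c1 - s * axis))
    if s < 0 and radial <= radius:
        return "top"
    if s > span and radial <= radius:
        return "bottom"
    rec_heavy = model.heavy_indices(model.roles.get("receptor"))
    dmin = float(np.min(np.linalg.norm(coords[rec_heavy] - cen, axis=1)))
    return "groove" if dmin <= groove_dist else "unbound"


def analyze_binding_modes(
    traj: Trajectory,
    contact_cutoff: float = CONTACT_CUTOFF,
    min_contacts: int = STABLE_MIN_CONTACTS,
    cluster_cutoff: float = CLUSTER_CUTOFF,
    min_population: float = MIN_POPULATION,
) -> BindingModeResult:
    """Full mode analysis: stability mask, Daura clustering of stable poses,
    population filter, and per-family mode classification."""
    series = stable_complex_mask(traj, contact_cutoff, min_contacts)
    result = BindingModeResult(contact_series=series,
                               n_stable=int(series.stable.sum()))
    if result.n_stable == 0:
        return result
    matrix, sel = pairwise_ligand_rmsd_matrix(traj, series.stable)
    families = daura_cluster(matrix, cluster_cutoff, frame_indices=sel)
    families = filter_population(families, min_population)
    for fam in families:
        fam.mode = classify_mode(traj.frames[fam.centroid], traj.model)
    result.families = families
    pops: dict[str, float] = {}
    for fam in families:
        pops[fam.mode] = pops.get(fam.mode, 0.0) + fam.population
    result.mode_populations = pops
    return result
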