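"""Geometry kernels: superposition, RMSD, plane fits, dihedrals, distances.

All coordinates are Å, all angles degrees.  These kernels are shared by the
binding-mode, order-parameter and energetics stages and carry no trajectory
state of their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "RigidTransform",
    "kabsch_superpose",
    "rmsd",
    "rmsd_after_fit",
    "fit_plane",
    "dihedral_angle",
    "interplane_angle",
]


class GeometryError(ValueError):
    """Degenerate geometry (collinear points, zero vectors, ...)."""


@dataclass
class RigidTransform:
    """Proper rotation + translation, applied as ``x @ rotation.T + translation``."""

    rotation: np.ndarray   # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unweighted, unfitted) RMSD between matched coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | list[int] | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The SVD closed form with reflection correction: the returned transform is a
    proper rotation (det = +1) plus translation minimising the RMSD over the
    selected points.  Returns (transform, rmsd over the selection after
    fitting).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        sel_m, sel_r = mobile, reference
    else:
        selection = np.asarray(selection, dtype=int)
        if selection.size == 0:
            raise GeometryError("empty selection")
        sel_m, sel_r = mobile[selection], reference[selection]
    if sel_m.shape != sel_r.shape:
        raise GeometryError("selection size mismatch between mobile and reference")
    if sel_m.shape[0] < 3:
        raise GeometryError("need at least 3 points for superposition")
    cm = sel_m.mean(axis=0)
    cr = sel_r.mean(axis=0)
    pm = sel_m - cm
    pr = sel_r - cr
    # collinearity check: rank of the centred cloud
    if np.linalg.matrix_rank(pm, tol=1e-8) < 2 or np.linalg.matrix_rank(pr, tol=1e-8) < 2:
        raise GeometryError("selected points are collinear; superposition is degenerate")
    h = pm.T @ pr
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cr - rot @ cm
    tf = RigidTransform(rotation=rot, translation=trans)
    return tf, rmsd(tf.apply(sel_m), sel_r)


def rmsd_after_fit(
    frame_coords: np.ndarray,
    reference_coords: np.ndarray,
    fit_selection: np.ndarray | list[int],
    measure_selection: np.ndarray | list[int],
) -> float:
    """Superpose on ``fit_selection`` only, then report RMSD over
    ``measure_selection`` with no further fitting (e.g. receptor-fit ligand
    RMSD)."""
    tf, _ = kabsch_superpose(frame_coords, reference_coords, fit_selection)
    moved = tf.apply(np.asarray(frame_coords, dtype=float))
    ms = np.asarray(measure_selection, dtype=int)
    return rmsd(moved[ms], np.asarray(reference_coords, dtype=float)[ms])


def fit_plane(
    points: np.ndarray, orient_axis: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through >= 3 points.

    Returns (unit normal, centroid).  The normal is the singular direction of
    smallest scatter.  If ``orient_axis`` is given (e.g. the 5'->3' tetrad
    stack axis) the normal sign is chosen to have a positive component along
    it; otherwise the sign is fixed by the largest-magnitude component being
    positive.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise GeometryError("need at least 3 points to fit a plane")
    centroid = points.mean(axis=0)
    centered = points - centroid
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise GeometryError("points are collinear; plane is degenerate")
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    if orient_axis is not None:
        if float(normal @ np.asarray(orient_axis, dtype=float)) < 0:
            normal = -normal
    elif normal[np.argmax(np.abs(normal))] < 0:
        normal = -normal
    return normal / np.linalg.norm(normal), centroid


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle of the four points, degrees in (-180, 180].

    IUPAC sign convention: looking down the p2->p3 bond, a clockwise rotation
    of p4 relative to p1 is positive (cis = 0, trans = 180).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-10:
            raise GeometryError("zero-length bond vector in dihedral")
    b1u = b2 / np.linalg.norm(b2)
    v = -b1 - (-b1 @ b1u) * b1u
    w = b3 - (b3 @ b1u) * b1u
    x = float(v @ w)
    y = float(np.cross(b1u, v) @ w)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def interplane_angle(normal_a: np.ndarray, normal_b: np.ndarray) -> float:
    """Angle between two planes, folded to [0, 90] degrees (orientation-free)."""
    na = np.asarray(normal_a, dtype=float)
    nb = np.asarray(normal_b, dtype=float)
    la, lb = np.linalg.norm(na), np.linalg.norm(nb)
    if la < 1e-12 or lb < 1e-12:
        raise GeometryError("zero-length normal vector")
    c = abs(float(na @ nb) / (la * lb))
    return float(np.degrees(np.arccos(min(1.0, c))))
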