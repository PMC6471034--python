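"""MM-GBSA binding-energy engine: LJ + Coulomb + HCT generalized Born + SASA.

The binding energy of a pose ensemble is estimated end-point style from three
trajectories (complex, receptor alone, ligand alone)::

    dE = E_complex - E_DNA_free - E_lig_free                           (total)
    dE = dE_vdw + dE_sur + dE_gbele + dE_conformation                  (parts)
    dE_x = E_x_complex - E_x_DNA_in_complex - E_x_lig_in_complex
    dE_conformation = <E_DNA_from_complex> + <E_lig_from_complex>
                      - <E_DNA_free> - <E_lig_free>

where GBELE combines vacuum Coulomb and the generalized-Born polar solvation
term, SUR is surface tension x SASA, and entropy is deliberately not
estimated (relative ranking of poses assumes comparable entropic terms).

The GB model is the Hawkins-Cramer-Truhlar pairwise-descreening form (the
classic "GB1" lineage): effective Born radii from the closed-form descreening
integral with a 0.09 Å radius offset, polar energy from the Still expression
with the exp(-0.73 kappa f) Debye-Hückel salt screening factor at 0.15 M.
SASA uses deterministic Shrake-Rupley sphere sampling (golden-spiral points)
with the LJ rmin/2 values as atomic radii and a 1.4 Å probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as sc
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structio import Frame, StructureModel, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "GBSettings",
    "EnergyDecomposition",
    "lj_energy",
    "coulomb_energy",
    "hct_born_radii",
    "gb_polar_energy",
    "sasa",
    "surface_energy",
    "species_energy",
    "mmgbsa_binding",
    "mmgbsa_single_trajectory",
    "delta_delta_g",
]

COULOMB_CONSTANT = 332.0637  # kcal Å / (mol e²)
SCEE = 1.0 / 1.2             # 1-4 electrostatic scale
SCNB = 0.5                   # 1-4 LJ scale


@dataclass
class GBSettings:
    """Generalized-Born / surface-area settings."""

    interior_dielectric: float = 1.0
    exterior_dielectric: float = 78.5
    salt_molar: float = 0.15            # mol/L
    surface_tension: float = 0.0072     # kcal/(mol Å²)
    radius_offset: float = 0.09         # Å subtracted from intrinsic radii
    probe_radius: float = 1.4           # Å
    temperature: float = 298.15         # K, for the Debye kappa
    sasa_points: int = 960

    def __post_init__(self) -> None:
        if self.interior_dielectric <= 0 or self.exterior_dielectric <= 0:
            raise ValueError("dielectrics must be positive")
        if self.salt_molar < 0:
            raise ValueError("salt concentration must be >= 0")

    @property
    def kappa(self) -> float:
        """Debye screening constant, Å⁻¹, from the salt concentration."""
        if self.salt_molar == 0:
            return 0.0
        # kappa² = 2 N_A e² I·1000 / (eps0 epsr kB T)   [SI], converted to Å⁻¹
        k2 = (2.0 * sc.N_A * sc.e**2 * self.salt_molar * 1000.0
              / (sc.epsilon_0 * self.exterior_dielectric
                 * sc.k * self.temperature))
        return math.sqrt(k2) * 1e-10


@dataclass
class EnergyDecomposition:
    """Per-component binding energy (means ± sd over the frame window)."""

    dE_vdw: float
    dE_sur: float
    dE_gbele: float
    dE_conformation: float
    sd: dict[str, float] = field(default_factory=dict)
    n_frames: int = 0
    per_frame: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def dE(self) -> float:
        return self.dE_vdw + self.dE_sur + self.dE_gbele + self.dE_conformation

    def as_dict(self) -> dict[str, float]:
        return {
            "dE_vdw": self.dE_vdw, "dE_sur": self.dE_sur,
            "dE_gbele": self.dE_gbele, "dE_conf": self.dE_conformation,
            "dE": self.dE,
        }


# ---------------------------------------------------------------------------
# pairwise scale matrices (cached per model identity)
# ---------------------------------------------------------------------------

def _pair_scales(model: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    cached = getattr(model, "_pair_scale_cache", None)
    if cached is not None:
        return cached
    n = model.n_atoms
    s_lj = np.ones((n, n))
    s_qq = np.ones((n, n))
    np.fill_diagonal(s_lj, 0.0)
    np.fill_diagonal(s_qq, 0.0)
    for pair in model.excluded_pairs:
        i, j = tuple(pair)
        s_lj[i, j] = s_lj[j, i] = 0.0
        s_qq[i, j] = s_qq[j, i] = 0.0
    for pair in model.pairs14:
        i, j = tuple(pair)
        s_lj[i, j] = s_lj[j, i] = SCNB
        s_qq[i, j] = s_qq[j, i] = SCEE
    model._pair_scale_cache = (s_lj, s_qq)
    return s_lj, s_qq


def lj_energy(frame: Frame, model: StructureModel) -> float:
    """12-6 Lennard-Jones over non-excluded pairs, AMBER combination rules
    (rmin = rmin_i/2 + rmin_j/2, eps = sqrt(eps_i eps_j)), 1-4 pairs x 0.5,
    no cutoff."""
    s_lj, _ = _pair_scales(model)
    rh = np.array([a.lj_rmin_half for a in model.atoms])
    ep = np.array([a.lj_epsilon for a in model.atoms])
    r = cdist(frame.coordinates, frame.coordinates)
    bad = (r < 1e-8) & (s_lj > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"coincident non-excluded atoms {i} and {j}")
    r = np.where(s_lj > 0, r, 1.0)
    rmin = rh[:, None] + rh[None, :]
    eps = np.sqrt(ep[:, None] * ep[None, :])
    x6 = (rmin / r) ** 6
    e = eps * (x6 * x6 - 2.0 * x6)
    return float(0.5 * np.sum(s_lj * e))


def coulomb_energy(frame: Frame, model: StructureModel) -> float:
    """Vacuum Coulomb sum over non-excluded pairs, 1-4 pairs x 1/1.2."""
    _, s_qq = _pair_scales(model)
    q = np.array([a.charge for a in model.atoms])
    r = cdist(frame.coordinates, frame.coordinates)
    qq = np.outer(q, q)
    bad = (r < 1e-8) & (s_qq > 0) & (np.abs(qq) > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"coincident charged atoms {i} and {j}")
    r = np.where(s_qq > 0, r, 1.0)
    return float(0.5 * COULOMB_CONSTANT * np.sum(s_qq * qq / r))


def hct_born_radii(frame: Frame, model: StructureModel,
                   settings: GBSettings | None = None) -> np.ndarray:
    """Effective Born radii by HCT pairwise descreening.

    1/R_i = 1/rho_i - sum_j I(rho_i, S_j rho_j, r_ij), with rho the intrinsic
    radius minus the offset and I the closed-form descreening integral
    (including the engulfed-atom case).  Radii are clamped to >= 0.1 Å.
    """
    settings = settings or GBSettings()
    rho = np.array([a.gb_radius for a in model.atoms]) - settings.radius_offset
    if np.any(rho <= 0):
        bad = int(np.argmin(rho))
        raise ValueError(f"atom {bad} has non-positive descreened radius")
    scale = np.array([a.gb_scale for a in model.atoms])
    s = scale * rho
    r = cdist(frame.coordinates, frame.coordinates)
    n = model.n_atoms
    rho_i = rho[:, None]
    s_j = s[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        U = r + s_j
        L = np.maximum(rho_i, np.abs(r - s_j))
        invL = 1.0 / L
        invU = 1.0 / U
        term = (
            0.5 * (invL - invU)
            + 0.25 / np.maximum(r, 1e-12) * np.log(L / U)
            + (s_j**2 - r**2) / (8.0 * np.maximum(r, 1e-12)) * (invL**2 - invU**2)
        )
        engulfed = (s_j - r) > rho_i
        extra = np.where(engulfed, 1.0 / rho_i - invL, 0.0)
        integral = np.where(rho_i >= U, 0.0, term + extra)
    np.fill_diagonal(integral, 0.0)
    inv_radius = 1.0 / rho - integral.sum(axis=1)
    radii = np.where(inv_radius > 1e-8, 1.0 / np.maximum(inv_radius, 1e-8), 1e8)
    return np.maximum(radii, 0.1)


def gb_polar_energy(frame: Frame, model: StructureModel,
                    born_radii: np.ndarray | None = None,
                    settings: GBSettings | None = None) -> float:
    """Polar solvation via the Still pairwise expression with salt screening.

    E = -(k_e/2) sum_ij (1/eps_in - exp(-0.73 kappa f_ij)/eps_out)
        q_i q_j / f_ij,  f_ij = sqrt(r² + R_i R_j exp(-r²/(4 R_i R_j))),
    over all ordered pairs including the i = j self terms (f_ii = R_i).
    """
    settings = settings or GBSettings()
    if born_radii is None:
        born_radii = hct_born_radii(frame, model, settings)
    q = np.array([a.charge for a in model.atoms])
    r2 = cdist(frame.coordinates, frame.coordinates) ** 2
    rr = np.outer(born_radii, born_radii)
    f = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    kappa = settings.kappa
    screen = (np.exp(-0.73 * kappa * f) if kappa > 0 else 1.0)
    prefac = 1.0 / settings.interior_dielectric - screen / settings.exterior_dielectric
    return float(-0.5 * COULOMB_CONSTANT * np.sum(prefac * np.outer(q, q) / f))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral points on the unit sphere."""
    k = np.arange(n) + 0.5
    z = 1.0 - 2.0 * k / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def sasa(frame: Frame, model: StructureModel, probe: float = 1.4,
         n_points: int = 960,
         radii: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area.

    Atomic radii default to the LJ rmin/2 values; each atom's sphere of radius
    (r_i + probe) is sampled with a deterministic golden-spiral point set and
    points inside any neighbour's expanded sphere are discarded.
    Returns (total Å², per-atom Å²).
    """
    if radii is None:
        radii = np.array([a.lj_rmin_half for a in model.atoms])
    radii = np.asarray(radii, dtype=float) + probe
    xyz = frame.coordinates
    n = len(radii)
    unit = _sphere_points(n_points)
    tree = cKDTree(xyz)
    areas = np.zeros(n)
    rmax = radii.max()
    for i in range(n):
        pts = xyz[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(xyz[i], radii[i] + rmax)
                     if j != i]
        if neighbors:
            d = cdist(pts, xyz[neighbors])
            buried = (d < radii[neighbors][None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * frac
    return float(areas.sum()), areas


def surface_energy(sasa_total: float,
                   surface_tension: float = 0.0072) -> float:
    """Nonpolar solvation term: surface tension x SASA."""
    if sasa_total < 0:
        raise ValueError("SASA must be >= 0")
    return surface_tension * sasa_total


def species_energy(frame: Frame, model: StructureModel,
                   settings: GBSettings | None = None) -> dict[str, float]:
    """All energy components of one species in one frame (kcal/mol)."""
    settings = settings or GBSettings()
    e_vdw = lj_energy(frame, model)
    e_coul = coulomb_energy(frame, model)
    radii = hct_born_radii(frame, model, settings)
    e_gb = gb_polar_energy(frame, model, radii, settings)
    total_area, _ = sasa(frame, model, settings.probe_radius,
                         settings.sasa_points)
    e_sur = surface_energy(total_area, settings.surface_tension)
    return {
        "vdw": e_vdw,
        "gbele": e_coul + e_gb,
        "sur": e_sur,
        "total": e_vdw + e_coul + e_gb + e_sur,
    }


def _window_indices(n: int, frame_window: tuple[float, float]) -> np.ndarray:
    lo, hi = frame_window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("frame window must satisfy 0 <= lo < hi <= 1")
    idx = np.arange(int(math.floor(lo * n)), int(math.ceil(hi * n)))
    if idx.size == 0:
        raise ValueError("empty frame window")
    return idx


def _check_mapping(sub_model: StructureModel, free_model: StructureModel,
                   label: str) -> None:
    if sub_model.n_atoms != free_model.n_atoms:
        raise ValueError(
            f"{label} topology mismatch: {sub_model.n_atoms} atoms in complex "
            f"vs {free_model.n_atoms} free"
        )
    for a, b in zip(sub_model.atoms, free_model.atoms):
        if a.name != b.name:
            raise ValueError(
                f"{label} atom mismatch at index {a.index}: {a.name} vs {b.name}"
            )


def mmgbsa_binding(
    complex_traj: Trajectory,
    dna_traj: Trajectory | None = None,
    ligand_traj: Trajectory | None = None,
    settings: GBSettings | None = None,
    frame_window: tuple[float, float] = (0.6, 1.0),
    max_frames: int | None = None,
) -> EnergyDecomposition:
    """Three-trajectory MM-GBSA decomposition over a frame window.

    Component terms (vdw, sur, gbele) are computed frame-by-frame on the
    complex trajectory as complex minus receptor-in-complex minus
    ligand-in-complex; the conformation term compares the mean total energies
    of the free receptor/ligand trajectories with their in-complex
    counterparts, and vanishes identically when the free trajectories are the
    in-complex sub-frames (single-trajectory protocol).
    """
    settings = settings or GBSettings()
    model = complex_traj.model
    rec_idx = model.role_indices("receptor")
    lig_idx = model.role_indices("ligand")
    if rec_idx.size == 0 or lig_idx.size == 0:
        raise ValueError("complex roles must define receptor and ligand")
    # energetics strips everything that is neither receptor nor ligand (ions)
    rec_sub = complex_traj.subset(list(rec_idx))
    lig_sub = complex_traj.subset(list(lig_idx))
    comp_sub = complex_traj.subset(list(rec_idx) + list(lig_idx))

    idx = _window_indices(len(complex_traj), frame_window)
    if max_frames is not None and idx.size > max_frames:
        idx = idx[np.linspace(0, idx.size - 1, max_frames).astype(int)]

    comp = {k: [] for k in ("vdw", "gbele", "sur", "total")}
    rec_c = {k: [] for k in ("vdw", "gbele", "sur", "total")}
    lig_c = {k: [] for k in ("vdw", "gbele", "sur", "total")}
    for fi in idx:
        for store, sub in ((comp, comp_sub), (rec_c, rec_sub), (lig_c, lig_sub)):
            e = species_energy(sub.frames[fi], sub.model, settings)
            for k in store:
                store[k].append(e[k])
    per_frame = {
        f"dE_{k}": np.array(comp[k]) - np.array(rec_c[k]) - np.array(lig_c[k])
        for k in ("vdw", "gbele", "sur")
    }

    # conformation term from the free-species trajectories
    def _free_mean(free_traj, sub_model, from_complex, label):
        if free_traj is None:
            return float(np.mean(from_complex))
        _check_mapping(sub_model, free_traj.model, label)
        fidx = _window_indices(len(free_traj), frame_window)
        if max_frames is not None and fidx.size > max_frames:
            fidx = fidx[np.linspace(0, fidx.size - 1, max_frames).astype(int)]
        vals = [species_energy(free_traj.frames[i], free_traj.model, settings)["total"]
                for i in fidx]
        return float(np.mean(vals))

    e_dna_from_complex = float(np.mean(rec_c["total"]))
    e_lig_from_complex = float(np.mean(lig_c["total"]))
    e_dna_free = _free_mean(dna_traj, rec_sub.model, rec_c["total"], "receptor")
    e_lig_free = _free_mean(ligand_traj, lig_sub.model, lig_c["total"], "ligand")
    d_conf = (e_dna_from_complex + e_lig_from_complex
              - e_dna_free - e_lig_free)
    if dna_traj is None and ligand_traj is None:
        d_conf = 0.0  # exact cancellation by definition

    result = EnergyDecomposition(
        dE_vdw=float(np.mean(per_frame["dE_vdw"])),
        dE_sur=float(np.mean(per_frame["dE_sur"])),
        dE_gbele=float(np.mean(per_frame["dE_gbele"])),
        dE_conformation=d_conf,
        sd={
            "dE_vdw": float(np.std(per_frame["dE_vdw"])),
            "dE_sur": float(np.std(per_frame["dE_sur"])),
            "dE_gbele": float(np.std(per_frame["dE_gbele"])),
            "dE": float(np.std(per_frame["dE_vdw"] + per_frame["dE_sur"]
                               + per_frame["dE_gbele"])),
        },
        n_frames=int(idx.size),
        per_frame=per_frame,
    )
    # decomposition identity (must hold to numerical precision)
    total = (result.dE_vdw + result.dE_sur + result.dE_gbele
             + result.dE_conformation)
    assert abs(total - result.dE) < 1e-10
    return result


def mmgbsa_single_trajectory(
    complex_traj: Trajectory,
    settings: GBSettings | None = None,
    frame_window: tuple[float, float] = (0.6, 1.0),
    max_frames: int | None = None,
) -> EnergyDecomposition:
    """Single-trajectory protocol: free species are the in-complex sub-frames,
    so the conformation term is exactly zero and dE is interaction-only."""
    return mmgbsa_binding(complex_traj, None, None, settings,
                          frame_window, max_frames)


def delta_delta_g(mode_energies: dict[str, float]):
    """Rank binding modes by mean dE; ddG is each mode's offset from the best
    (most negative) mode.  Ties order alphabetically."""
    import pandas as pd

    if not mode_energies:
        raise ValueError("need at least one mode")
    best = min(mode_energies.values())
    rows = [
        {"mode": mode, "dE": e, "ddG": e - best}
        for mode, e in mode_energies.items()
    ]
    return (pd.DataFrame(rows)
            .sort_values(["dE", "mode"], kind="stable")
            .reset_index(drop=True))
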