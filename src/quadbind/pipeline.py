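"""End-to-end analysis: modes -> order parameters -> energetics -> report.

``run_pipeline`` executes the full analysis on one trajectory with every
threshold collected in a single auditable :class:`RunConfig`: stable-complex
detection, Daura clustering and mode classification, the five order
parameters, per-mode single-trajectory MM-GBSA, and the ddG ranking.  All
intermediates are written as TSV files stamped with a config fingerprint so
every reported number is reproducible from persisted per-frame data.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binding_modes as bm
from . import energetics as en
from . import order_parameters as op
from .structio import (
    StructureError,
    Trajectory,
    read_annotations,
    read_multimodel_pdb,
    read_parameter_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "Report", "load_trajectory", "run_pipeline",
           "render_energy_table"]


@dataclass
class RunConfig:
    """Every input path and threshold for one pipeline run."""

    trajectory: str = ""
    parameters: str = ""
    annotations: str = ""
    out_dir: str = "quadbind_out"
    contact_cutoff: float = 3.0      # Å
    stable_min_contacts: int = 11    # stable ⇔ contacts > 10
    cluster_cutoff: float = 2.0      # Å ligand RMSD
    min_population: float = 0.01
    hbond_dist: float = 3.5          # Å
    hbond_angle: float = 120.0       # deg
    salt_molar: float = 0.15
    surface_tension: float = 0.0072
    frame_window: tuple[float, float] = (0.6, 1.0)
    energy_max_frames: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "cluster_cutoff", "min_population",
                     "hbond_dist", "hbond_angle", "surface_tension"):
            if getattr(self, name) <= 0:
                raise StructureError(f"threshold {name} must be positive")
        self.frame_window = tuple(self.frame_window)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["frame_window"] = list(self.frame_window)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    def fingerprint(self) -> str:
        doc = asdict(self)
        doc["frame_window"] = list(self.frame_window)
        blob = yaml.safe_dump(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class Report:
    """Outputs of one pipeline run."""

    populations: pd.DataFrame
    energies: pd.DataFrame
    ddg: pd.DataFrame
    order_parameters: pd.DataFrame
    families: pd.DataFrame
    no_stable_complex: bool = False
    fingerprint: str = ""
    paths: dict[str, str] = field(default_factory=dict)


def load_trajectory(config: RunConfig) -> Trajectory:
    """Read frames (with CONECT bonds), parameters and annotations."""
    traj = read_multimodel_pdb(config.trajectory)
    read_parameter_table(config.parameters, traj.model)
    read_annotations(config.annotations, traj.model)
    return traj


def _write_tsv(df: pd.DataFrame, path: Path, fingerprint: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config {fingerprint}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(traj: Trajectory, config: RunConfig) -> Report:
    """Run every analysis stage on an in-memory trajectory.

    A run with zero stable frames is a legitimate outcome: the report carries
    an explicit ``no_stable_complex`` flag and empty tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fp = config.fingerprint()
    config.to_yaml(out / "config.yaml")

    logger.info("stage 1: stable-complex detection (cutoff %.2f Å, > %d contacts)",
                config.contact_cutoff, config.stable_min_contacts - 1)
    result = bm.analyze_binding_modes(
        traj,
        contact_cutoff=config.contact_cutoff,
        min_contacts=config.stable_min_contacts,
        cluster_cutoff=config.cluster_cutoff,
        min_population=config.min_population,
    )
    contacts = pd.DataFrame({
        "frame": np.arange(len(traj)),
        "contacts": result.contact_series.counts,
        "stable": result.contact_series.stable.astype(int),
    })
    _write_tsv(contacts, out / "contacts.tsv", fp)

    fam_rows = [
        {"family": k, "centroid_frame": f.centroid, "n_members": f.members.size,
         "population": f.population, "mode": f.mode}
        for k, f in enumerate(result.families)
    ]
    families = pd.DataFrame(
        fam_rows, columns=["family", "centroid_frame", "n_members",
                           "population", "mode"])
    _write_tsv(families, out / "families.tsv", fp)

    pops = pd.DataFrame(
        [{"mode": m, "population": p}
         for m, p in sorted(result.mode_populations.items())],
        columns=["mode", "population"])
    _write_tsv(pops, out / "modes.tsv", fp)

    logger.info("stage 2: order parameters over %d frames", len(traj))
    ops = op.order_parameter_series(traj)
    _write_tsv(ops, out / "orderparams.tsv", fp)

    no_stable = result.n_stable == 0
    energy_rows = []
    frame_rows = []
    mode_means: dict[str, float] = {}
    if not no_stable:
        logger.info("stage 3: MM-GBSA per mode (salt %.2f M, gamma %.4f)",
                    config.salt_molar, config.surface_tension)
        settings = en.GBSettings(salt_molar=config.salt_molar,
                                 surface_tension=config.surface_tension)
        mode_frames: dict[str, list[int]] = {}
        for fam in result.families:
            if fam.mode in ("top", "bottom", "groove"):
                mode_frames.setdefault(fam.mode, []).extend(fam.members.tolist())
        for mode, frames_ in sorted(mode_frames.items()):
            frames_ = sorted(frames_)
            if len(frames_) > config.energy_max_frames:
                pick = np.linspace(0, len(frames_) - 1,
                                   config.energy_max_frames).astype(int)
                frames_ = [frames_[i] for i in pick]
            sub = Trajectory(model=traj.model,
                             frames=[traj.frames[i] for i in frames_])
            dec = en.mmgbsa_single_trajectory(sub, settings,
                                              frame_window=(0.0, 1.0))
            row = {"mode": mode, **dec.as_dict()}
            row.update({f"sd_{k}": v for k, v in dec.sd.items()})
            row["n_frames"] = dec.n_frames
            energy_rows.append(row)
            mode_means[mode] = dec.dE
            for k, fi in enumerate(frames_[:dec.n_frames]):
                frame_rows.append({
                    "mode": mode, "frame": fi,
                    "dE_vdw": dec.per_frame["dE_vdw"][k],
                    "dE_sur": dec.per_frame["dE_sur"][k],
                    "dE_gbele": dec.per_frame["dE_gbele"][k],
                })
    energies = pd.DataFrame(energy_rows)
    _write_tsv(energies, out / "energy.tsv", fp)
    _write_tsv(pd.DataFrame(frame_rows), out / "energy_frames.tsv", fp)

    if mode_means:
        ddg = en.delta_delta_g(mode_means)
    else:
        ddg = pd.DataFrame(columns=["mode", "dE", "ddG"])
    _write_tsv(ddg, out / "ddg.tsv", fp)

    report = Report(
        populations=pops, energies=energies, ddg=ddg,
        order_parameters=ops, families=families,
        no_stable_complex=no_stable, fingerprint=fp,
        paths={p.stem: str(p) for p in out.glob("*.tsv")},
    )
    if no_stable:
        logger.info("no stable complex found; empty mode/energy tables")
    return report


def render_energy_table(report: Report) -> str:
    """Human-readable per-mode energy table; flags the largest-magnitude
    component of each mode."""
    if report.energies.empty:
        return "mode\tdE_vdw\tdE_sur\tdE_gbele\tdE_conf\tdE\tdominant\n"
    lines = ["mode\tdE_vdw\tdE_sur\tdE_gbele\tdE_conf\tdE\tdominant"]
    comps = ("dE_vdw", "dE_sur", "dE_gbele", "dE_conf")
    for _, row in report.energies.iterrows():
        dominant = max(comps, key=lambda c: abs(row[c]))
        vals = "\t".join(f"{row[c]:.3f}" for c in comps + ("dE",))
        lines.append(f"{row['mode']}\t{vals}\t{dominant}")
    return "\n".join(lines) + "\n"
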