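"""Structures, trajectories and their plain-text file formats.

The shared data model for the whole package: a :class:`StructureModel` holds
atoms with force-field-style parameters (partial charge, Lennard-Jones
``rmin/2`` and ``epsilon``, intrinsic Born radius and HCT descreening scale),
a bond list with derived 1-2/1-3 exclusions and 1-4 pairs, a role partition
(receptor / ligand / ion), and the G-tetrad / channel-ion annotations that the
binding-mode and order-parameter analyses consume.

Trajectories are carried as multi-model PDB (fixed-width, ``MODEL``/``ENDMDL``
delimited), parameters as a whitespace-delimited sidecar table and annotations
as a small YAML document.  Coordinates are Å, charges in units of the
elementary charge, energies kcal/mol.  Indices are 0-based in memory and
1-based in every file written.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Frame",
    "Trajectory",
    "StructureError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_parameter_table",
    "write_parameter_table",
    "read_annotations",
    "write_annotations",
    "build_exclusions",
]


class StructureError(ValueError):
    """Raised for malformed structures, parameter tables or annotations."""


@dataclass
class AtomRecord:
    """One atom with identity and nonbonded parameters."""

    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str = "A"
    charge: float = 0.0
    lj_rmin_half: float = 0.0   # Å
    lj_epsilon: float = 0.0     # kcal/mol
    gb_radius: float = 1.5      # intrinsic Born radius, Å (mBondi-style)
    gb_scale: float = 0.8       # HCT descreening scale, dimensionless

    def validate(self) -> None:
        if not self.element:
            raise StructureError(f"atom {self.index} ({self.name}) has empty element")
        if self.gb_radius <= 0:
            raise StructureError(
                f"atom {self.index} ({self.residue_name}/{self.name}) has gb_radius <= 0"
            )
        if self.lj_epsilon < 0:
            raise StructureError(
                f"atom {self.index} ({self.residue_name}/{self.name}) has negative epsilon"
            )


@dataclass
class StructureModel:
    """Atoms, bonded topology, roles and quadruplex annotations for one system."""

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    # exclusions: frozenset pairs excluded from nonbonded sums (1-2 and 1-3)
    excluded_pairs: set[frozenset[int]] = field(default_factory=set)
    # 1-4 pairs flagged for scaled interactions
    pairs14: set[frozenset[int]] = field(default_factory=set)
    roles: dict[str, set[int]] = field(default_factory=dict)
    tetrads: list[list[int]] = field(default_factory=list)  # residue indices
    channel_ions: list[int] = field(default_factory=list)   # atom indices
    ligand_core: list[int] = field(default_factory=list)    # atom indices
    topology_label: str = ""

    # -- basic selections -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def role_indices(self, role: str) -> np.ndarray:
        return np.array(sorted(self.roles.get(role, set())), dtype=int)

    def residue_atoms(self, residue_index: int) -> list[int]:
        return [a.index for a in self.atoms if a.residue_index == residue_index]

    def atom_index(self, residue_index: int, name: str) -> int | None:
        for a in self.atoms:
            if a.residue_index == residue_index and a.name == name:
                return a.index
        return None

    BACKBONE_NAMES = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'")

    def backbone_indices(self) -> np.ndarray:
        """Receptor sugar-phosphate backbone atoms (alignment selection)."""
        recv = self.roles.get("receptor", set())
        return np.array(
            [a.index for a in self.atoms
             if a.index in recv and a.name in self.BACKBONE_NAMES],
            dtype=int,
        )

    def heavy_indices(self, subset: Iterable[int] | None = None) -> np.ndarray:
        pool = set(subset) if subset is not None else set(range(self.n_atoms))
        return np.array(
            [a.index for a in self.atoms if a.index in pool and a.element != "H"],
            dtype=int,
        )

    def validate(self) -> None:
        for a in self.atoms:
            a.validate()
        seen = set()
        for a in self.atoms:
            key = (a.residue_index, a.name)
            if key in seen:
                raise StructureError(f"duplicate atom {a.name} in residue {a.residue_index}")
            seen.add(key)
        if self.roles:
            all_assigned: set[int] = set()
            for role, idx in self.roles.items():
                if all_assigned & idx:
                    raise StructureError(f"role {role} overlaps another role")
                all_assigned |= idx
            if all_assigned != set(range(self.n_atoms)):
                raise StructureError("roles do not partition all atoms")
        for tet in self.tetrads:
            if len(tet) not in (2, 4):
                raise StructureError(
                    "each tetrad must name 4 residues (2 for duplex pseudo-tetrads)"
                )
        for i, j in self.bonds:
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise StructureError(f"bond ({i}, {j}) references unknown atom index")


@dataclass
class Frame:
    """Coordinates for every atom at one time point."""

    coordinates: np.ndarray  # (n_atoms, 3), Å
    time: float = 0.0        # ps

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError("frame coordinates must be (n, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureError("frame contains non-finite coordinates")


@dataclass
class Trajectory:
    """Ordered frames over one StructureModel."""

    model: StructureModel
    frames: list[Frame]

    def __post_init__(self) -> None:
        n = self.model.n_atoms
        for k, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise StructureError(
                    f"frame {k} has {fr.coordinates.shape[0]} atoms, model has {n}"
                )
        times = [fr.time for fr in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise StructureError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate array."""
        return np.stack([fr.coordinates for fr in self.frames])

    def subset(self, atom_indices: Sequence[int]) -> "Trajectory":
        """Sub-trajectory over a subset of atoms (indices remapped, roles dropped)."""
        atom_indices = list(atom_indices)
        remap = {old: new for new, old in enumerate(atom_indices)}
        atoms = [
            replace(self.model.atoms[old], index=new)
            for new, old in enumerate(atom_indices)
        ]
        keep = set(atom_indices)
        bonds = [
            (remap[i], remap[j]) for i, j in self.model.bonds if i in keep and j in keep
        ]
        sub = StructureModel(atoms=atoms, bonds=bonds)
        build_exclusions(sub)
        frames = [
            Frame(fr.coordinates[atom_indices], time=fr.time) for fr in self.frames
        ]
        return Trajectory(model=sub, frames=frames)


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray]:
    name = line[12:16].strip()
    resname = line[17:20].strip() or line[17:21].strip()
    chain = line[21].strip() or "A"
    try:
        resseq = int(line[22:26])
    except ValueError as exc:
        raise StructureError(f"line {lineno}: unparseable residue number") from exc
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise StructureError(f"line {lineno}: unparseable coordinate field") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name[:1]
    rec = AtomRecord(
        index=-1, name=name, element=element,
        residue_index=resseq - 1, residue_name=resname, chain_id=chain,
    )
    return rec, np.array([x, y, z])


def read_multimodel_pdb(path) -> Trajectory:
    """Read a fixed-width, MODEL/ENDMDL-delimited (or single-model) PDB.

    Every MODEL becomes one :class:`Frame`; the atom roster must be identical
    across models.  Frame times are taken from a ``REMARK 250 TIME_PS`` line
    when present, otherwise 50-ps spacing is assumed (one saved frame per
    50 ps).
    """
    atoms: list[AtomRecord] | None = None
    frames: list[Frame] = []
    cur_atoms: list[AtomRecord] = []
    cur_xyz: list[np.ndarray] = []
    cur_time: float | None = None
    model_idx = 0
    in_model = False
    saw_model_records = False
    conect: set[tuple[int, int]] = set()

    def close_model() -> None:
        nonlocal atoms, cur_atoms, cur_xyz, cur_time
        if not cur_atoms:
            return
        if atoms is None:
            atoms = [replace(a, index=i) for i, a in enumerate(cur_atoms)]
        else:
            if len(cur_atoms) != len(atoms):
                raise StructureError(
                    f"model {model_idx} has {len(cur_atoms)} atoms, "
                    f"expected {len(atoms)}"
                )
            for i, (a, b) in enumerate(zip(atoms, cur_atoms)):
                if (a.name, a.residue_index) != (b.name, b.residue_index):
                    raise StructureError(
                        f"model {model_idx} atom {i} is {b.name}, expected {a.name}"
                    )
        t = cur_time if cur_time is not None else 50.0 * len(frames)
        frames.append(Frame(np.array(cur_xyz), time=t))
        cur_atoms, cur_xyz, cur_time = [], [], None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_records = True
                in_model = True
                try:
                    model_idx = int(line[6:].split()[0])
                except (ValueError, IndexError):
                    model_idx = len(frames) + 1
            elif rec == "ENDMDL":
                close_model()
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                a, xyz = _parse_atom_line(line, lineno)
                cur_atoms.append(a)
                cur_xyz.append(xyz)
            elif line.startswith("REMARK 250 TIME_PS"):
                try:
                    cur_time = float(line.split()[-1])
                except ValueError:
                    pass
            elif rec == "CONECT":
                fields = line[6:].split()
                try:
                    serials = [int(x) for x in fields]
                except ValueError as exc:
                    raise StructureError(
                        f"line {lineno}: unparseable CONECT record") from exc
                for partner in serials[1:]:
                    pair = (min(serials[0], partner) - 1,
                            max(serials[0], partner) - 1)
                    if pair not in conect:
                        conect.add(pair)
    if cur_atoms:
        if saw_model_records and in_model:
            raise StructureError(f"model {model_idx} not closed by ENDMDL")
        model_idx += 1
        close_model()
    if atoms is None:
        raise StructureError(f"no atoms found in {path}")
    model = StructureModel(atoms=atoms, bonds=sorted(conect))
    if model.bonds:
        build_exclusions(model)
    return Trajectory(model=model, frames=frames)


def write_multimodel_pdb(path, traj: Trajectory, remarks: Sequence[str] = ()) -> None:
    """Write a trajectory as fixed-width multi-model PDB (1-based numbering)."""
    model = traj.model
    hetero = set(model.roles.get("ligand", set())) | set(model.roles.get("ion", set()))
    with open(path, "w") as fh:
        for rem in remarks:
            fh.write(f"REMARK   1 {rem}\n")
        for k, fr in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {k:4d}\n")
            fh.write(f"REMARK 250 TIME_PS {fr.time:.3f}\n")
            for a, xyz in zip(model.atoms, fr.coordinates):
                record = "HETATM" if a.index in hetero else "ATOM  "
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    f"{record}{(a.index % 99999) + 1:5d} {name:<4s} "
                    f"{a.residue_name:<3s} {a.chain_id:1s}"
                    f"{(a.residue_index % 9999) + 1:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        partners: dict[int, list[int]] = {}
        for i, j in sorted(
            (min(i, j), max(i, j)) for i, j in model.bonds
        ):
            partners.setdefault(i, []).append(j)
        for i, js in partners.items():
            for k in range(0, len(js), 4):
                row = "".join(f"{j + 1:5d}" for j in js[k:k + 4])
                fh.write(f"CONECT{i + 1:5d}{row}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Parameter table
# ---------------------------------------------------------------------------

PARAM_HEADER = "residue_name atom_name charge rmin_half epsilon gb_radius gb_scale"


def read_parameter_table(path, model: StructureModel) -> StructureModel:
    """Populate atom parameters from a whitespace-delimited sidecar table.

    Every atom must be matched by its (residue_name, atom_name) pair; a
    missing or duplicate row is a hard error.
    """
    table: dict[tuple[str, str], tuple[float, ...]] = {}
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    for ln in lines[1:]:  # one header line
        parts = ln.split()
        if len(parts) != 7:
            raise StructureError(f"malformed parameter row: {ln.strip()!r}")
        key = (parts[0], parts[1])
        if key in table:
            raise StructureError(f"duplicate parameter row for {key[0]}/{key[1]}")
        table[key] = tuple(float(x) for x in parts[2:])
    missing = []
    for a in model.atoms:
        key = (a.residue_name, a.name)
        if key not in table:
            missing.append(f"{a.residue_name}/{a.name} (atom {a.index})")
            continue
        q, rmh, eps, rgb, sgb = table[key]
        a.charge, a.lj_rmin_half, a.lj_epsilon, a.gb_radius, a.gb_scale = (
            q, rmh, eps, rgb, sgb,
        )
    if missing:
        raise StructureError("no parameters for: " + ", ".join(missing))
    for a in model.atoms:
        a.validate()
    return model


def write_parameter_table(path, rows: Iterable[tuple]) -> None:
    """Write rows of (resname, atomname, charge, rmin_half, eps, gb_r, gb_s)."""
    with open(path, "w") as fh:
        fh.write(PARAM_HEADER + "\n")
        for r in rows:
            fh.write(
                f"{r[0]:<4s} {r[1]:<4s} {r[2]:10.5f} {r[3]:8.4f} "
                f"{r[4]:9.5f} {r[5]:7.4f} {r[6]:7.4f}\n"
            )


# ---------------------------------------------------------------------------
# Annotations (YAML)
# ---------------------------------------------------------------------------

def read_annotations(path, model: StructureModel) -> StructureModel:
    """Apply a YAML annotation file: roles, tetrads, channel ions, ligand core.

    Residue and atom indices in the file are 1-based.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    roles = doc.get("roles", {})
    if roles:
        res_role = {}
        for role, residues in roles.items():
            for r in residues:
                res_role[int(r) - 1] = role
        model.roles = {}
        for a in model.atoms:
            role = res_role.get(a.residue_index)
            if role is None:
                raise StructureError(
                    f"residue {a.residue_index + 1} has no role in annotation file"
                )
            model.roles.setdefault(role, set()).add(a.index)
    model.tetrads = [[int(r) - 1 for r in tet] for tet in doc.get("tetrads", [])]
    model.channel_ions = [int(i) - 1 for i in doc.get("channel_ions", [])]
    if "ligand_core" in doc:
        model.ligand_core = [int(i) - 1 for i in doc["ligand_core"]]
    model.topology_label = doc.get("topology", model.topology_label)
    model.validate()
    return model


def write_annotations(path, model: StructureModel) -> None:
    res_by_role: dict[str, set[int]] = {}
    for role, idx in model.roles.items():
        res_by_role[role] = sorted(
            {model.atoms[i].residue_index + 1 for i in idx}
        )
    doc = {
        "roles": {k: list(v) for k, v in res_by_role.items()},
        "tetrads": [[r + 1 for r in tet] for tet in model.tetrads],
        "channel_ions": [i + 1 for i in model.channel_ions],
        "ligand_core": [i + 1 for i in model.ligand_core],
        "topology": model.topology_label,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

def build_exclusions(model: StructureModel) -> StructureModel:
    """Derive 1-2/1-3 excluded pairs and the scaled 1-4 pair set from bonds.

    A pair's class is its shortest bond-path length: 1 or 2 bonds -> excluded,
    exactly 3 bonds -> 1-4.  Computed by breadth-first search to depth 3 from
    every atom.
    """
    n = model.n_atoms
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in model.bonds:
        if not (0 <= i < n and 0 <= j < n):
            raise StructureError(f"bond ({i}, {j}) references unknown atom index")
        adj[i].add(j)
        adj[j].add(i)
    excluded: set[frozenset[int]] = set()
    pairs14: set[frozenset[int]] = set()
    for start in range(n):
        dist = {start: 0}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            if dist[u] == 3:
                continue
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for v, d in dist.items():
            if v == start:
                continue
            if d <= 2:
                excluded.add(frozenset((start, v)))
            elif d == 3:
                pairs14.add(frozenset((start, v)))
    model.excluded_pairs = excluded
    model.pairs14 = pairs14
    return model
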