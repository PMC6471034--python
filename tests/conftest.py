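import numpy as np
import pytest

from quadbind import synthetic_data as sd
from quadbind.structio import AtomRecord, StructureModel, Frame, build_exclusions


@pytest.fixture(scope="session")
def quadruplex():
    return sd.build_quadruplex()


@pytest.fixture(scope="session")
def duplex():
    return sd.build_duplex()


@pytest.fixture(scope="session")
def ligand():
    return sd.build_ligand()


@pytest.fixture(scope="session")
def bound_trajectory(quadruplex, ligand):
    """Short planted trajectory: unbound -> approach -> groove -> top, with
    one scripted base flip on the first loop thymine."""
    script = sd.TrajectoryScript(
        segments=[(20, "unbound", 0.3), (10, "approach", 0.3),
                  (90, "groove", 0.3), (60, "top", 0.3)],
        flips=[(5, 50, 120)], seed=11)
    traj, truth, flips = sd.generate_trajectory(quadruplex, ligand, script)
    return traj, truth, flips


def toy_model(params, bonds=()):
    """Small ad-hoc model: params is a list of
    (charge, rmin_half, epsilon, gb_radius, gb_scale) tuples."""
    atoms = [
        AtomRecord(index=i, name=f"X{i}", element="C", residue_index=0,
                   residue_name="TOY", charge=p[0], lj_rmin_half=p[1],
                   lj_epsilon=p[2], gb_radius=p[3], gb_scale=p[4])
        for i, p in enumerate(params)
    ]
    model = StructureModel(atoms=atoms, bonds=list(bonds))
    build_exclusions(model)
    return model


def frame_of(coords):
    return Frame(np.asarray(coords, dtype=float))
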