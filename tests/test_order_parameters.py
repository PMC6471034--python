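"""Hydrogen bonds, binding observables, torsions and base-flip detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from quadbind import order_parameters as op
from quadbind import synthetic_data as sd
from quadbind.geometry import dihedral_angle
from quadbind.structio import Frame, Trajectory

from conftest import frame_of, toy_model


def _dha_frame(d_a_dist, angle_deg, dh=1.0):
    """Donor at origin, H on the x axis, acceptor at the given D-A distance
    so that the D-H-A angle equals angle_deg."""
    d = np.zeros(3)
    h = np.array([dh, 0.0, 0.0])
    # H->A direction making the requested D-H-A angle with H->D = (-1, 0, 0);
    # the H-A length follows from the law of cosines for the fixed |DA|
    cos_h = np.cos(np.radians(angle_deg))
    direction = np.array([-cos_h, np.sin(np.radians(angle_deg)), 0.0])
    ha = dh * cos_h + np.sqrt((dh * cos_h) ** 2 - dh ** 2 + d_a_dist ** 2)
    a = h + ha * direction
    assert np.linalg.norm(a - d) == pytest.approx(d_a_dist, abs=1e-9)
    return frame_of([d, h, a])


class TestHydrogenBonds:
    def test_within_both_cutoffs(self):
        fr = _dha_frame(3.4, 170.0)
        assert len(op.hydrogen_bonds(fr, [(0, 1)], [2])) == 1

    def test_distance_criterion(self):
        fr = _dha_frame(3.6, 180.0)
        assert op.hydrogen_bonds(fr, [(0, 1)], [2]) == []

    def test_angle_criterion(self):
        fr = _dha_frame(3.0, 100.0)
        assert op.hydrogen_bonds(fr, [(0, 1)], [2]) == []

    def test_unbonded_donor_pair_rejected(self):
        fr = frame_of([[0, 0, 0], [5, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="not bonded"):
            op.hydrogen_bonds(fr, [(0, 1)], [2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_random_geometries_against_literal_recheck(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0, 2, 3)
        h = d + rng.normal(0, 0.5, 3) * 0.4 + np.array([1.0, 0, 0])
        a = rng.normal(0, 3, 3)
        fr = frame_of([d, h, a])
        bonds = op.hydrogen_bonds(fr, [(0, 1)], [2])
        v1, v2 = d - h, a - h
        ang = np.degrees(np.arccos(np.clip(
            v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1)))
        expected = (np.linalg.norm(d - a) <= 3.5) and (ang >= 120.0)
        assert bool(bonds) == expected


class TestTetradHbonds:
    def test_ideal_tetrads_have_eight_bonds(self, quadruplex):
        model, frame = quadruplex
        for tetrad in model.tetrads:
            assert op.tetrad_hbond_count(frame, model, tetrad) == 8

    def test_displaced_guanine_breaks_half_the_cycle(self, quadruplex):
        model, frame = quadruplex
        tetrad = model.tetrads[0]
        xyz = frame.coordinates.copy()
        res_atoms = [a.index for a in model.atoms
                     if a.residue_index == tetrad[0]]
        xyz[res_atoms] += np.array([10.0, 0, 0])
        assert op.tetrad_hbond_count(Frame(xyz), model, tetrad) <= 4

    def test_non_guanine_residue_rejected(self, quadruplex):
        model, frame = quadruplex
        with pytest.raises(ValueError, match="not guanine"):
            op.tetrad_hbond_count(frame, model, [0, 4, 5, 6])


class TestWatsonCrick:
    def test_each_gc_pair_has_three_bonds(self, duplex):
        model, frame = duplex
        res_of = {a.index: a.residue_index for a in model.atoms}
        n_bp = 20
        for bp in (0, 1, 9, 19):
            pair = [bp, 2 * n_bp - 1 - bp]
            donors, acceptors = op.default_donors_acceptors(model, pair)
            bonds = [b for b in op.hydrogen_bonds(frame, donors, acceptors)
                     if res_of[b[0]] != res_of[b[2]]]
            assert len(bonds) == 3


class TestDistances:
    def test_center_to_center_closed_form(self):
        fr = frame_of([[0, 0, 0], [3, 4, 0]])
        assert op.center_to_center(fr, [0], [1]) == pytest.approx(5.0)

    def test_identical_groups_zero(self):
        fr = frame_of([[1, 2, 3], [4, 5, 6]])
        assert op.center_to_center(fr, [0, 1], [0, 1]) == pytest.approx(0.0)

    def test_empty_group_rejected(self):
        fr = frame_of([[0, 0, 0]])
        with pytest.raises(ValueError, match="nonempty"):
            op.center_to_center(fr, [], [0])

    def test_ion_distance_and_arity(self, quadruplex):
        model, frame = quadruplex
        d = op.ion_ion_distance(frame, model.channel_ions)
        assert d == pytest.approx(3.4, abs=0.1)  # generator rise
        with pytest.raises(ValueError, match="exactly 2"):
            op.ion_ion_distance(frame, model.channel_ions[:1])

    def test_r_monotone_during_approach(self, quadruplex, ligand):
        script = sd.TrajectoryScript(
            segments=[(5, "unbound", 0.0), (20, "approach", 0.0),
                      (5, "top", 0.0)], seed=1)
        traj, truth, _ = sd.generate_trajectory(quadruplex, ligand, script)
        series = op.order_parameter_series(traj)
        approach = series[truth["state"] == "approach"]["R"].to_numpy()
        assert np.all(np.diff(approach) <= 1e-9)


class TestOrderParameterSeries:
    def test_first_frame_rmsd_is_zero(self, bound_trajectory):
        traj, _, _ = bound_trajectory
        sub = Trajectory(model=traj.model, frames=traj.frames[:4])
        series = op.order_parameter_series(sub)
        assert series["rmsd_receptor"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert series["rmsd_ligand"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert set(series.columns) >= {"hb_t1", "hb_t2", "hb_t3", "angle_deg",
                                       "rmsd_receptor", "rmsd_ligand", "R",
                                       "dKK"}
        assert (series["angle_deg"].dropna() <= 90.0).all()
        assert (series["angle_deg"].dropna() >= 0.0).all()

    def test_stacked_pose_is_coplanar_with_tetrad(self, quadruplex, ligand):
        script = sd.TrajectoryScript(segments=[(2, "top", 0.0)], seed=0)
        traj, _, _ = sd.generate_trajectory(quadruplex, ligand, script)
        series = op.order_parameter_series(traj)
        assert (series["angle_deg"] < 5.0).all()


class TestBackboneTorsions:
    def test_delta_in_canonical_b_range(self, duplex):
        model, frame = duplex
        traj = Trajectory(model=model, frames=[frame])
        for residue in (1, 2, 10, 21):
            prof = op.backbone_torsions(traj, residue)
            delta = prof.table["delta"].iloc[0]
            assert 120.0 <= delta <= 160.0

    def test_five_prime_terminal_missing_alpha_beta(self, duplex):
        model, frame = duplex
        traj = Trajectory(model=model, frames=[frame])
        prof = op.backbone_torsions(traj, 0)
        assert np.isnan(prof.table["alpha"].iloc[0])
        assert np.isnan(prof.table["beta"].iloc[0])
        assert not np.isnan(prof.table["delta"].iloc[0])

    def test_three_prime_terminal_missing_eps_zeta(self, duplex):
        model, frame = duplex
        traj = Trajectory(model=model, frames=[frame])
        prof = op.backbone_torsions(traj, 19)  # chain A 3' end
        assert np.isnan(prof.table["eps"].iloc[0])
        assert np.isnan(prof.table["zeta"].iloc[0])

    def test_equals_dihedral_on_named_quadruple(self, duplex):
        model, frame = duplex
        traj = Trajectory(model=model, frames=[frame])
        prof = op.backbone_torsions(traj, 2)
        idx = {(a.residue_index, a.name): a.index for a in model.atoms}
        quad = [idx[(2, "C5'")], idx[(2, "C4'")], idx[(2, "C3'")],
                idx[(2, "O3'")]]
        expected = dihedral_angle(*(frame.coordinates[i] for i in quad))
        assert prof.table["delta"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_invariant_under_rigid_motion(self, duplex):
        from scipy.spatial.transform import Rotation

        model, frame = duplex
        rot = Rotation.from_euler("xyz", [20, -35, 110],
                                  degrees=True).as_matrix()
        moved = Frame(frame.coordinates @ rot.T + np.array([5.0, -3.0, 2.0]))
        t1 = Trajectory(model=model, frames=[frame])
        t2 = Trajectory(model=model, frames=[moved])
        p1 = op.backbone_torsions(t1, 5).table
        p2 = op.backbone_torsions(t2, 5).table
        pd.testing.assert_frame_equal(p1, p2, atol=1e-7, check_exact=False)


class TestTorsionHistogram:
    def test_identical_angles_fill_one_bin(self):
        table = pd.DataFrame({"frame": range(50)})
        for angle in list(op.TORSION_ATOMS) + ["chi"]:
            table[angle] = 47.0
        prof = op.TorsionProfile(residue=0, table=table)
        hists = op.torsion_histogram(prof)
        for counts, edges in hists.values():
            assert counts.sum() == 50 and (counts > 0).sum() == 1

    def test_uniform_draw_within_multinomial_bounds(self):
        rng = np.random.default_rng(30)
        n = 10_000
        table = pd.DataFrame({"frame": range(n)})
        for angle in list(op.TORSION_ATOMS) + ["chi"]:
            table[angle] = rng.uniform(-180, 180, n)
        prof = op.TorsionProfile(residue=0, table=table)
        hists = op.torsion_histogram(prof, bin_width=10.0)
        n_bins = 36
        expect = n / n_bins
        sigma = np.sqrt(n * (1 / n_bins) * (1 - 1 / n_bins))
        for counts, _ in hists.values():
            assert np.all(np.abs(counts - expect) < 5 * sigma)

    def test_empty_window(self):
        table = pd.DataFrame({"frame": range(10)})
        for angle in list(op.TORSION_ATOMS) + ["chi"]:
            table[angle] = 0.0
        prof = op.TorsionProfile(residue=0, table=table)
        hists = op.torsion_histogram(prof, window=slice(10, 10))
        assert all(c.sum() == 0 for c, _ in hists.values())


class TestBaseFlips:
    def test_planted_flip_recovered(self, bound_trajectory):
        traj, _, flips = bound_trajectory
        residue, f_out, f_in = flips[0]
        intervals, _ = op.detect_base_flips(traj, residue)
        assert len(intervals) == 1
        out, back = intervals[0]
        assert abs(out - f_out) <= 5
        assert abs(back - f_in) <= 5

    def test_rigid_trajectory_has_no_flips(self, quadruplex, ligand):
        script = sd.TrajectoryScript(segments=[(30, "top", 0.0)], seed=0)
        traj, _, _ = sd.generate_trajectory(quadruplex, ligand, script)
        intervals, _ = op.detect_base_flips(traj, 5)
        assert intervals == []

    def test_open_interval_at_trajectory_end(self, quadruplex, ligand):
        script = sd.TrajectoryScript(segments=[(60, "top", 0.0)],
                                     flips=[(5, 20, None)], seed=0)
        traj, _, _ = sd.generate_trajectory(quadruplex, ligand, script)
        intervals, _ = op.detect_base_flips(traj, 5)
        assert len(intervals) == 1
        out, back = intervals[0]
        assert abs(out - 20) <= 5 and back is None
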