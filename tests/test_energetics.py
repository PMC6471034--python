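"""MM, generalized-Born and surface-area terms against independent oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from quadbind import energetics as en
from quadbind import synthetic_data as sd
from quadbind.structio import Frame, Trajectory

from conftest import frame_of, toy_model


def hct_integral_oracle(rho_i, s_j, r):
    """Numerical quadrature of the pairwise descreening volume integral
    (1/4pi) \\int_{V_j \\ sphere_i} s^-4 dV, reduced analytically over the two
    angular coordinates to a 1-D radial integral."""
    if rho_i >= r + s_j:
        return 0.0
    full = 0.0
    lo = max(rho_i, abs(r - s_j))
    if s_j - r > rho_i:
        full = 1.0 / rho_i - 1.0 / (s_j - r)
        lo = s_j - r

    def cap_fraction_over_s2(s):
        return (s_j ** 2 - (r - s) ** 2) / (4.0 * r * s ** 3)

    cap, _ = quad(cap_fraction_over_s2, lo, r + s_j, limit=400)
    return full + cap


class TestLennardJones:
    def test_minimum_at_rmin(self):
        m = toy_model([(0, 1.0, 0.2, 1.5, 0.8)] * 2)
        assert en.lj_energy(frame_of([[0, 0, 0], [2.0, 0, 0]]), m) == \
            pytest.approx(-0.2)

    def test_zero_at_sigma(self):
        m = toy_model([(0, 1.0, 0.2, 1.5, 0.8)] * 2)
        sigma = 2.0 / 2 ** (1 / 6)
        assert en.lj_energy(frame_of([[0, 0, 0], [sigma, 0, 0]]), m) == \
            pytest.approx(0.0, abs=1e-12)

    def test_cluster_matches_double_loop(self):
        rng = np.random.default_rng(40)
        params = [(rng.uniform(-1, 1), rng.uniform(0.8, 2.0),
                   rng.uniform(0.01, 0.3), 1.5, 0.8) for _ in range(8)]
        bonds = [(0, 1), (1, 2), (2, 3), (3, 4)]
        m = toy_model(params, bonds)
        x = rng.uniform(0, 6, (8, 3))
        elj = ec = 0.0
        for i in range(8):
            for j in range(i + 1, 8):
                pair = frozenset((i, j))
                s_lj = 0.0 if pair in m.excluded_pairs else \
                    (0.5 if pair in m.pairs14 else 1.0)
                s_qq = 0.0 if pair in m.excluded_pairs else \
                    (1 / 1.2 if pair in m.pairs14 else 1.0)
                r = np.linalg.norm(x[i] - x[j])
                rmin = m.atoms[i].lj_rmin_half + m.atoms[j].lj_rmin_half
                eps = math.sqrt(m.atoms[i].lj_epsilon * m.atoms[j].lj_epsilon)
                elj += s_lj * eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
                ec += s_qq * en.COULOMB_CONSTANT * \
                    m.atoms[i].charge * m.atoms[j].charge / r
        fr = frame_of(x)
        assert en.lj_energy(fr, m) == pytest.approx(elj, abs=1e-10)
        assert en.coulomb_energy(fr, m) == pytest.approx(ec, abs=1e-10)


class TestCoulomb:
    def test_unit_charges_at_one_angstrom(self):
        m = toy_model([(1.0, 1.0, 0.0, 1.5, 0.8)] * 2)
        assert en.coulomb_energy(frame_of([[0, 0, 0], [1, 0, 0]]), m) == \
            pytest.approx(332.0637)

    def test_neutral_system_is_zero(self):
        m = toy_model([(0.0, 1.0, 0.1, 1.5, 0.8)] * 4)
        fr = frame_of(np.random.default_rng(1).uniform(0, 5, (4, 3)))
        assert en.coulomb_energy(fr, m) == 0.0

    def test_coincident_charges_rejected(self):
        m = toy_model([(1.0, 1.0, 0.0, 1.5, 0.8)] * 2)
        with pytest.raises(ValueError, match="coincident"):
            en.coulomb_energy(frame_of([[0, 0, 0], [0, 0, 0]]), m)


class TestBornRadii:
    def test_isolated_atom_is_descaled_intrinsic(self):
        m = toy_model([(0, 1.0, 0.1, 1.5, 0.8)])
        radii = en.hct_born_radii(frame_of([[0, 0, 0]]), m)
        assert radii[0] == pytest.approx(1.5 - 0.09)

    def test_far_pair_limits_to_isolated(self):
        m = toy_model([(0, 1.0, 0.1, 1.5, 0.8), (0, 1.0, 0.1, 1.2, 0.85)])
        radii = en.hct_born_radii(frame_of([[0, 0, 0], [500.0, 0, 0]]), m)
        assert radii[0] == pytest.approx(1.41, abs=1e-4)
        assert radii[1] == pytest.approx(1.11, abs=1e-4)

    @pytest.mark.parametrize("r", [1.0, 1.5, 2.0, 3.0, 5.0])
    def test_pair_matches_descreening_quadrature(self, r):
        m = toy_model([(0, 1.0, 0.1, 1.5, 0.80), (0, 1.0, 0.1, 1.2, 0.85)])
        radii = en.hct_born_radii(frame_of([[0, 0, 0], [r, 0, 0]]), m)
        rho1, rho2 = 1.5 - 0.09, 1.2 - 0.09
        inv1 = 1 / rho1 - hct_integral_oracle(rho1, 0.85 * rho2, r)
        inv2 = 1 / rho2 - hct_integral_oracle(rho2, 0.80 * rho1, r)
        assert radii[0] == pytest.approx(1 / inv1, abs=1e-3)
        assert radii[1] == pytest.approx(1 / inv2, abs=1e-3)

    def test_nonpositive_descaled_radius_rejected(self):
        m = toy_model([(0, 1.0, 0.1, 0.05, 0.8)])
        with pytest.raises(ValueError, match="non-positive"):
            en.hct_born_radii(frame_of([[0, 0, 0]]), m)


class TestGBPolar:
    def test_born_formula_limit(self):
        m = toy_model([(1.0, 1.7, 0.1, 2.09, 0.8)])  # descaled radius 2.0
        settings = en.GBSettings(salt_molar=0.0)
        e = en.gb_polar_energy(frame_of([[0, 0, 0]]), m, settings=settings)
        born = -0.5 * en.COULOMB_CONSTANT * (1 - 1 / 78.5) / 2.0
        assert e == pytest.approx(born, rel=1e-6)

    def test_zero_charges_zero_energy(self):
        m = toy_model([(0.0, 1.0, 0.1, 1.5, 0.8)] * 3)
        fr = frame_of(np.random.default_rng(2).uniform(0, 4, (3, 3)))
        assert en.gb_polar_energy(fr, m) == pytest.approx(0.0, abs=1e-12)

    def test_two_atoms_match_independent_still_expression(self):
        q1, q2, r = 0.5, -0.8, 2.5
        m = toy_model([(q1, 1.0, 0.1, 1.6, 0.8), (q2, 1.0, 0.1, 1.3, 0.85)])
        fr = frame_of([[0, 0, 0], [r, 0, 0]])
        settings = en.GBSettings()
        radii = en.hct_born_radii(fr, m, settings)
        # independent single-purpose evaluation
        kappa = settings.kappa
        total = 0.0
        for (qi, ri), (qj, rj), dij in (
            ((q1, radii[0]), (q1, radii[0]), 0.0),
            ((q2, radii[1]), (q2, radii[1]), 0.0),
            ((q1, radii[0]), (q2, radii[1]), r),
        ):
            f = math.sqrt(dij ** 2 + ri * rj *
                          math.exp(-dij ** 2 / (4 * ri * rj)))
            pref = 1.0 - math.exp(-0.73 * kappa * f) / 78.5
            w = 1.0 if dij == 0 else 2.0  # off-diagonal counted twice
            total += -0.5 * en.COULOMB_CONSTANT * pref * qi * qj / f * w
        e = en.gb_polar_energy(fr, m, radii, settings)
        assert e == pytest.approx(total, abs=1e-10)

    def test_salt_deepens_single_ion_polar_energy(self):
        # ionic screening adds to the dielectric screening: the Debye factor
        # exp(-0.73 kappa f) < 1 makes the polar term strictly more negative
        # for a single ion, approaching the kappa -> inf bound -k q^2/(2a)
        rng = np.random.default_rng(3)
        for _ in range(10):
            q = rng.uniform(-1, 1)
            a = rng.uniform(1.0, 2.5)
            m = toy_model([(q, 1.0, 0.1, a + 0.09, 0.8)])
            fr = frame_of([[0, 0, 0]])
            e0 = en.gb_polar_energy(fr, m, settings=en.GBSettings(salt_molar=0.0))
            es = en.gb_polar_energy(fr, m,
                                    settings=en.GBSettings(salt_molar=0.15))
            bound = -0.5 * en.COULOMB_CONSTANT * q * q / a
            assert es <= e0 + 1e-12
            assert e0 <= 1e-12
            assert bound <= es <= 0


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        m = toy_model([(0, 1.6, 0.1, 1.5, 0.8)])
        total, _ = en.sasa(frame_of([[0, 0, 0]]), m)
        exact = 4 * math.pi * (1.6 + 1.4) ** 2
        assert total == pytest.approx(exact, rel=0.005)

    def test_fully_buried_atom_has_zero_area(self):
        # central small atom caged by 14 large neighbours
        params = [(0, 0.8, 0.1, 1.5, 0.8)] + [(0, 2.4, 0.1, 1.5, 0.8)] * 14
        m = toy_model(params)
        shell = [[0, 0, 0]]
        for axis in range(3):
            for sign in (-1, 1):
                v = [0, 0, 0]
                v[axis] = sign * 2.2
                shell.append(v)
        for sx in (-1, 1):
            for sy in (-1, 1):
                for sz in (-1, 1):
                    shell.append([1.4 * sx, 1.4 * sy, 1.4 * sz])
        _, areas = en.sasa(frame_of(shell), m)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_sphere_overlap_matches_cap_formula(self):
        m = toy_model([(0, 1.6, 0.1, 1.5, 0.8)] * 2)
        d = 3.0
        big_r = 1.6 + 1.4
        total, _ = en.sasa(frame_of([[0, 0, 0], [d, 0, 0]]), m)
        cap = 2 * math.pi * big_r * (big_r - d / 2)
        exact = 2 * (4 * math.pi * big_r ** 2 - cap)
        assert total == pytest.approx(exact, rel=0.005)

    def test_point_count_convergence(self, ligand):
        model, frame = ligand
        t1, _ = en.sasa(frame, model, n_points=960)
        t2, _ = en.sasa(frame, model, n_points=1920)
        assert abs(t2 - t1) / t2 < 0.002

    def test_surface_energy_linear(self):
        assert en.surface_energy(1000.0) == pytest.approx(7.2)
        assert en.surface_energy(0.0) == 0.0
        assert en.surface_energy(2000.0) == pytest.approx(2 * 7.2)


@pytest.fixture(scope="module")
def small_complex(quadruplex, ligand):
    script = sd.TrajectoryScript(segments=[(5, "top", 0.2)], seed=3)
    traj, _, _ = sd.generate_trajectory(quadruplex, ligand, script)
    return traj


class TestMMGBSA:
    def test_conformation_term_zero_for_identical_free_trajs(self, small_complex):
        traj = small_complex
        rec = traj.subset(list(traj.model.role_indices("receptor")))
        lig = traj.subset(list(traj.model.role_indices("ligand")))
        dec = en.mmgbsa_binding(traj, rec, lig, frame_window=(0.0, 1.0))
        assert dec.dE_conformation == pytest.approx(0.0, abs=1e-9)

    def test_decomposition_identity(self, small_complex):
        dec = en.mmgbsa_single_trajectory(small_complex,
                                          frame_window=(0.0, 1.0))
        assert dec.dE == pytest.approx(
            dec.dE_vdw + dec.dE_sur + dec.dE_gbele + dec.dE_conformation,
            abs=1e-10)

    def test_apolar_system_reduces_to_surface_term(self, small_complex):
        traj = small_complex
        import copy

        apolar = copy.deepcopy(traj)
        for a in apolar.model.atoms:
            a.charge = 0.0
            a.lj_epsilon = 0.0
        dec = en.mmgbsa_single_trajectory(apolar, frame_window=(0.0, 1.0))
        assert dec.dE_vdw == pytest.approx(0.0, abs=1e-12)
        assert dec.dE_gbele == pytest.approx(0.0, abs=1e-12)
        assert dec.dE == pytest.approx(dec.dE_sur, abs=1e-12)

    def test_means_match_per_frame_oracle(self, small_complex):
        traj = small_complex
        dec = en.mmgbsa_single_trajectory(traj, frame_window=(0.0, 1.0))
        rec_idx = list(traj.model.role_indices("receptor"))
        lig_idx = list(traj.model.role_indices("ligand"))
        comp = traj.subset(rec_idx + lig_idx)
        rec = traj.subset(rec_idx)
        lig = traj.subset(lig_idx)
        vdw = []
        for k in range(len(traj)):
            e = (en.lj_energy(comp.frames[k], comp.model)
                 - en.lj_energy(rec.frames[k], rec.model)
                 - en.lj_energy(lig.frames[k], lig.model))
            vdw.append(e)
        assert dec.dE_vdw == pytest.approx(np.mean(vdw), abs=1e-9)

    def test_distant_ligand_binds_nothing(self, quadruplex, ligand):
        script = sd.TrajectoryScript(segments=[(2, "unbound", 0.0)], seed=1)
        traj, _, _ = sd.generate_trajectory(quadruplex, ligand, script)
        dec = en.mmgbsa_single_trajectory(traj, frame_window=(0.0, 1.0))
        # +3/-37 net charges leave a small screened electrostatic tail at
        # 30 Å; vdW and surface terms vanish
        assert abs(dec.dE_vdw) < 0.01
        assert abs(dec.dE_sur) < 0.01
        assert abs(dec.dE) < 1.0

    def test_empty_window_rejected(self, small_complex):
        with pytest.raises(ValueError):
            en.mmgbsa_single_trajectory(small_complex,
                                        frame_window=(0.5, 0.5))

    def test_topology_mismatch_rejected(self, small_complex, ligand):
        lig_traj = Trajectory(model=ligand[0], frames=[ligand[1]])
        rec = small_complex.subset(
            list(small_complex.model.role_indices("receptor")))
        bad = rec.subset(list(range(rec.model.n_atoms - 1)))
        with pytest.raises(ValueError, match="mismatch"):
            en.mmgbsa_binding(small_complex, bad, lig_traj,
                              frame_window=(0.0, 1.0))


class TestDeltaDeltaG:
    def test_single_mode(self):
        table = en.delta_delta_g({"top": -10.0})
        assert table["ddG"].iloc[0] == 0.0

    def test_tie_broken_by_label(self):
        table = en.delta_delta_g({"b": -5.0, "a": -5.0})
        assert list(table["mode"]) == ["a", "b"]
        assert (table["ddG"] == 0.0).all()

    def test_ranking_is_ascending(self):
        table = en.delta_delta_g({"x": -10.0, "y": -30.0, "z": -20.0})
        assert list(table["mode"]) == ["y", "z", "x"]
        assert list(table["ddG"]) == [0.0, 10.0, 20.0]
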