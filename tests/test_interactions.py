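"""Energies, forces, torques: pair terms, Ewald, AA<->CG equivalence."""

import numpy as np
import pytest

from molcwater import units
from molcwater.fixtures import (cubic_lattice_water, dimer_scan, rocksalt)
from molcwater.forcefield import load_model
from molcwater.interactions import (InteractionError, aa_single_point,
                                    cg_single_point, coulomb_pair, ewald_eval,
                                    lj_pair)
from molcwater.rigid import (BeadState, Configuration, quat_multiply,
                             random_quaternions, reverse_map)

C = units.COULOMB


def _ion_state(P, q=None, charge=1.0):
    from molcwater.fixtures import point_ion_species
    sp = point_ion_species(charge)
    return BeadState(P=np.asarray(P, float),
                     q=np.array([1.0, 0, 0, 0]) if q is None else q,
                     species=sp)


class TestCoulombPair:
    def test_unit_charges_at_one_angstrom(self):
        s1 = _ion_state([0, 0, 0])
        s2 = _ion_state([1, 0, 0])
        res = coulomb_pair(1.0, 1.0, s1, 0, s2, 0)
        assert res.energy == pytest.approx(C)
        np.testing.assert_array_equal(res.T1, np.zeros(3))
        np.testing.assert_array_equal(res.T2, np.zeros(3))

    def test_newton_third_law_bit_exact(self, spce, rng):
        quats = random_quaternions(2, rng)
        s1 = BeadState(P=rng.normal(size=3), q=quats[0], species=spce)
        s2 = BeadState(P=rng.normal(size=3) + 5.0, q=quats[1], species=spce)
        res = coulomb_pair(0.4238, -0.8476, s1, 1, s2, 0)
        np.testing.assert_array_equal(res.F2, -res.F1)

    def test_torque_is_lever_arm_cross_force(self, tip4p, rng):
        from molcwater.rigid import site_positions
        quats = random_quaternions(2, rng)
        s1 = BeadState(P=np.zeros(3), q=quats[0], species=tip4p)
        s2 = BeadState(P=np.array([4.0, 1.0, -2.0]), q=quats[1], species=tip4p)
        res = coulomb_pair(0.5564, -1.1128, s1, 0, s2, 2)
        np.testing.assert_allclose(
            res.T1, np.cross(site_positions(s1)[0] - s1.P, res.F1), atol=1e-14)
        np.testing.assert_allclose(
            res.T2, np.cross(site_positions(s2)[2] - s2.P, res.F2), atol=1e-14)

    def test_force_and_torque_match_finite_differences(self, spce, rng):
        """Central-difference oracle on bead translation and body rotation."""
        quats = random_quaternions(2, rng)
        P2 = np.array([3.5, 0.7, -1.2])
        h = 1e-5

        def energy(P1, q1):
            s1 = BeadState(P=P1, q=q1, species=spce)
            s2 = BeadState(P=P2, q=quats[1], species=spce)
            return coulomb_pair(0.4238, 0.4238, s1, 1, s2, 2).energy

        P1 = np.zeros(3)
        res = coulomb_pair(
            0.4238, 0.4238, BeadState(P=P1, q=quats[0], species=spce), 1,
            BeadState(P=P2, q=quats[1], species=spce), 2)
        for ax in range(3):
            dP = np.zeros(3); dP[ax] = h
            fd = -(energy(P1 + dP, quats[0]) - energy(P1 - dP, quats[0])) / (2 * h)
            assert fd == pytest.approx(res.F1[ax], rel=1e-6, abs=1e-9)
        for ax in range(3):
            n = np.zeros(3); n[ax] = 1.0
            def rot(ang):
                dq = np.array([np.cos(ang / 2), *(np.sin(ang / 2) * n)])
                return quat_multiply(dq, quats[0])
            fd = -(energy(P1, rot(h)) - energy(P1, rot(-h))) / (2 * h)
            assert fd == pytest.approx(res.T1[ax], rel=1e-6, abs=1e-9)

    def test_coincident_sites_raise(self):
        s1 = _ion_state([0, 0, 0])
        s2 = _ion_state([0, 0, 0])
        with pytest.raises(InteractionError, match="[Cc]oincident"):
            coulomb_pair(1.0, -1.0, s1, 0, s2, 0)


class TestLennardJones:
    def test_zero_at_sigma(self):
        e, _ = lj_pair(3.166, 3.166, 0.1553, 10.0)
        assert e == pytest.approx(0.0, abs=1e-14)

    def test_minimum_depth_and_zero_force(self):
        r = 2 ** (1 / 6) * 3.166
        e, f = lj_pair(r, 3.166, 0.1553, 10.0)
        assert e == pytest.approx(-0.1553, rel=1e-12)
        assert f == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("r", [2.9, 3.2, 4.0, 5.5])
    def test_force_matches_derivative(self, r):
        h = 1e-6
        ep, _ = lj_pair(r + h, 3.166, 0.1553, 10.0)
        em, _ = lj_pair(r - h, 3.166, 0.1553, 10.0)
        _, f = lj_pair(r, 3.166, 0.1553, 10.0)
        assert f == pytest.approx(-(ep - em) / (2 * h), rel=1e-8)

    def test_shift_moves_energy_to_zero_at_cutoff(self):
        e, _ = lj_pair(9.999999, 3.166, 0.1553, 10.0, shift=True)
        e0, _ = lj_pair(9.999999, 3.166, 0.1553, 10.0, shift=False)
        ec = 4 * 0.1553 * ((3.166 / 10.0) ** 12 - (3.166 / 10.0) ** 6)
        assert e == pytest.approx(e0 - ec, rel=1e-12)

    def test_zero_distance_raises(self):
        with pytest.raises(InteractionError):
            lj_pair(0.0, 3.166, 0.1553, 10.0)


def _madelung_evjen(n=10):
    """Direct-summation oracle: Evjen's fractional-charge cube method."""
    idx = np.arange(-n, n + 1)
    gx, gy, gz = np.meshgrid(idx, idx, idx, indexing="ij")
    w = np.ones_like(gx, dtype=float)
    for g in (gx, gy, gz):
        w *= np.where(np.abs(g) == n, 0.5, 1.0)
    r = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
    sgn = (-1.0) ** (np.abs(gx) + np.abs(gy) + np.abs(gz))
    mask = r > 0
    return float((sgn[mask] * w[mask] / r[mask]).sum())


class TestEwald:
    def test_isolated_pair_in_large_box(self):
        """A +-1 e pair 2 A apart approaches the bare Coulomb energy as the
        box grows (the residual is the r^-3 dipole-image lattice sum)."""
        from molcwater.fixtures import point_ion_species
        plus, minus = point_ion_species(1.0), point_ion_species(-1.0)

        def pair_energy(L, r_cut):
            c = L / 2.0
            cfg = Configuration(P=np.array([[c - 1.0, c, c], [c + 1.0, c, c]]),
                                q=np.tile([1.0, 0, 0, 0], (2, 1)),
                                box=np.full(3, L), species=[plus, minus],
                                species_index=np.array([0, 1]))
            return ewald_eval(cfg, accuracy=1e-6, r_cut=r_cut).energy_coul

        assert pair_energy(60.0, 15.0) == pytest.approx(-C / 2.0, abs=2e-2)
        assert pair_energy(320.0, 80.0) == pytest.approx(-C / 2.0, abs=1e-4)

    def test_madelung_constant_against_direct_summation(self):
        a = 2.82
        cfg = rocksalt(a=a, n_cells=2)
        rep = ewald_eval(cfg, accuracy=1e-7, r_cut=5.0)
        per_pair = rep.energy_coul / (cfg.n_beads / 2)
        oracle = _madelung_evjen(10) * C / a  # Evjen sum is negative
        assert per_pair == pytest.approx(oracle, rel=1e-4)
        assert per_pair == pytest.approx(-1.747565 * C / a, rel=1e-4)

    def test_splitting_parameter_invariance(self):
        cfg = cubic_lattice_water("SPC-E", 27, 0.997, seed=3)
        acc = 1e-6
        from molcwater.interactions import EwaldParams
        alpha0 = EwaldParams.from_accuracy(acc, 4.5).alpha
        energies = [ewald_eval(cfg, accuracy=acc, r_cut=4.5,
                               alpha=alpha0 * f).energy_coul
                    for f in (1.0, 1.4, 2.0)]
        scale = max(abs(e) for e in energies)
        assert max(energies) - min(energies) < acc * scale * 10

    def test_neutral_system_forces_sum_to_zero(self):
        cfg = cubic_lattice_water("Tip4P-05", 27, 0.997, seed=5)
        rep = cg_single_point(cfg, r_cut=4.5, accuracy=1e-5)
        np.testing.assert_allclose(rep.forces.sum(axis=0), np.zeros(3),
                                   atol=1e-8)

    def test_charged_system_rejected(self):
        from molcwater.fixtures import point_ion_species
        sp = point_ion_species(1.0)
        cfg = Configuration(P=[[5.0, 5, 5]], q=[[1.0, 0, 0, 0]],
                            box=[10.0, 10, 10], species=[sp])
        with pytest.raises(InteractionError, match="neutral"):
            ewald_eval(cfg, r_cut=4.0)

    def test_cutoff_too_large_for_box_rejected(self):
        cfg = cubic_lattice_water("SPC-E", 8, 0.997, seed=1)
        with pytest.raises(InteractionError, match="cutoff"):
            cg_single_point(cfg, r_cut=20.0)


def _brute_force_cluster_energy(aa, r_cut_lj=1e9):
    """Hand-coded double loop over molecules and sites (isolated cluster)."""
    sp = aa.species
    e = 0.0
    lj_idx = sp.atom_sites.index(sp.lj_site)
    sig, eps = sp.lj_site.lj_sigma, sp.lj_site.lj_epsilon
    n = aa.n_molecules
    for i in range(n):
        for j in range(i + 1, n):
            for si in sp.atom_sites:
                for sj in sp.atom_sites:
                    if si.charge == 0.0 or sj.charge == 0.0:
                        continue
                    ri = aa.coords[i][sp.atom_sites.index(si)]
                    rj = aa.coords[j][sp.atom_sites.index(sj)]
                    r = np.linalg.norm(ri - rj)
                    e += C * si.charge * sj.charge / r
            r = np.linalg.norm(aa.coords[i][lj_idx] - aa.coords[j][lj_idx])
            if r < r_cut_lj:
                sr6 = (sig / r) ** 6
                e += 4 * eps * (sr6 * sr6 - sr6)
    return e


class TestSinglePoint:
    def test_single_bead_all_energies_zero(self, spce):
        cfg = Configuration(P=[[5.0, 5, 5]], q=[[1.0, 0, 0, 0]],
                            box=[60.0, 60, 60], species=[spce],
                            periodic=False)
        rep = cg_single_point(cfg)
        assert rep.energy_total == 0.0

    @pytest.mark.parametrize("model", ["SPC-E", "Tip3P-Ew", "Tip4P-05"])
    def test_dimer_scan_matches_brute_force(self, model):
        """Isolated-dimer energies against a plain double-loop sum."""
        for cfg in dimer_scan(model, separations=[2.8, 3.2, 4.0, 6.0], seed=9):
            aa = reverse_map(cfg)
            ref = _brute_force_cluster_energy(aa)
            got = cg_single_point(cfg).energy_total
            assert got == pytest.approx(ref, rel=1e-12, abs=1e-12)

    def test_aa_cg_identity_on_mapped_configuration(self, any_model):
        cfg = cubic_lattice_water(any_model, 27, 0.997, seed=11)
        cg = cg_single_point(cfg, r_cut=4.5, accuracy=1e-5)
        aa = aa_single_point(reverse_map(cfg), r_cut=4.5, accuracy=1e-5)
        assert aa.energy_total == pytest.approx(cg.energy_total, rel=1e-10)

    def test_far_separated_molecules_negligible_energy(self, spce):
        """The dimer interaction vanishes with separation (dipole tail ~r^-3:
        ~1e-3 kcal/mol at 50 A, below 1e-6 by 1000 A)."""
        e50 = cg_single_point(dimer_scan(spce, separations=[50.0],
                                         seed=2)[0]).energy_total
        far = dimer_scan(spce, separations=[1000.0], seed=2)[0]
        rep = cg_single_point(far)
        assert abs(e50) < 5e-3
        assert abs(rep.energy_total) < 1e-6
        assert abs(rep.energy_lj) < 1e-12

    def test_global_rotation_translation_invariance(self, tip4p, rng):
        cfg = dimer_scan(tip4p, separations=[3.1], seed=4)[0]
        e0 = cg_single_point(cfg).energy_total
        g = random_quaternions(1, rng)[0]
        t = rng.normal(size=3)
        from molcwater.rigid import quat_rotate
        moved = cfg.copy()
        moved.P = np.array([quat_rotate(g, p) for p in cfg.P]) + t + 200.0
        moved.q = quat_multiply(g, cfg.q)
        moved.box = np.full(3, 500.0)
        e1 = cg_single_point(moved).energy_total
        assert e1 == pytest.approx(e0, rel=1e-10)

    def test_isolated_dimer_angular_momentum_balance(self, any_model, rng):
        cfg = dimer_scan(any_model, separations=[3.0], seed=8)[0]
        rep = cg_single_point(cfg)
        total = (rep.torques + np.cross(cfg.P, rep.forces)).sum(axis=0)
        np.testing.assert_allclose(total, np.zeros(3), atol=1e-8)

    def test_energy_total_is_sum_of_components(self, spce):
        cfg = cubic_lattice_water(spce, 27, 0.997, seed=6)
        rep = cg_single_point(cfg, r_cut=4.5)
        assert rep.energy_total == pytest.approx(
            rep.energy_lj + rep.energy_coul_real + rep.energy_coul_recip
            + rep.energy_coul_self, abs=1e-12)


class TestVirial:
    def test_virial_trace_matches_volume_derivative(self, spce):
        """-dU/dV finite difference vs tr(W)/3V on a periodic configuration."""
        cfg = cubic_lattice_water(spce, 27, 1.05, seed=13)
        kw = dict(r_cut=4.0, accuracy=1e-7, lj_shift=True)
        rep = cg_single_point(cfg, **kw)
        h = 1e-5

        def u_at_scale(s):
            c = cfg.copy()
            c.P = cfg.P * s
            c.box = cfg.box * s
            return cg_single_point(c, **kw).energy_total

        du_ds = (u_at_scale(1 + h) - u_at_scale(1 - h)) / (2 * h)
        # W = -3V dU/dV = -s dU/ds at s=1
        assert np.trace(rep.virial) == pytest.approx(-du_ds, rel=2e-3,
                                                     abs=1e-3)
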