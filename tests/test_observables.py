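"""Observable estimators against analytic synthetic inputs."""

import math

import numpy as np
import pytest

from molcwater import units
from molcwater.fixtures import (ideal_gas_frame, random_walk_traj,
                                synthetic_stress_series)
from molcwater.observables import (ObservableError, density,
                                   enthalpy_vaporization, rdf, self_diffusion,
                                   stokes_einstein, surface_tension,
                                   viscosity_gk)
from molcwater.rigid import AAFrame
from molcwater.trajio import Trajectory, TrajectoryFrame


def _one_bead_traj(spce, box_edge=10.0, n_frames=1, energies=None,
                   pressure=None):
    traj = Trajectory(species=[spce])
    for i in range(n_frames):
        traj.append(TrajectoryFrame(
            step=i, time=float(i), box=np.full(3, box_edge),
            positions=np.array([[5.0, 5, 5]]),
            quats=np.array([[1.0, 0, 0, 0]]), vels=np.zeros((1, 3)),
            angmom=np.zeros((1, 3)), images=np.zeros((1, 3), int),
            energies=dict(energies) if energies else None,
            pressure=np.array(pressure) if pressure is not None else None))
    return traj


class TestDensity:
    def test_single_bead_unit_conversion(self, spce):
        """18.0154 g/mol in 1000 A^3 -> 0.02992 g/cm^3."""
        res = density(_one_bead_traj(spce))
        assert res.value == pytest.approx(0.02992, abs=1e-5)
        assert res.units == "g/cm^3"

    def test_duplicate_frames_leave_value_unchanged(self, spce):
        one = density(_one_bead_traj(spce, n_frames=2))
        two = density(_one_bead_traj(spce, n_frames=10))
        assert one.value == pytest.approx(two.value, rel=1e-14)
        assert two.uncertainty < 1e-15  # identical blocks (up to round-off)

    def test_empty_trajectory_rejected(self, spce):
        with pytest.raises(ObservableError, match="empty"):
            density(Trajectory(species=[spce]))


class TestRdf:
    def test_ideal_gas_is_unity(self, spce):
        frames = [ideal_gas_frame(spce, n=400, box=(25.0,) * 3, seed=s)
                  for s in range(4)]
        table = rdf(frames, pair="OO", dr=0.25)
        r, g = table[:, 0], table[:, 1]
        far = g[r > 4.0]
        assert abs(far.mean() - 1.0) < 0.02
        assert np.abs(far - 1.0).max() < 0.25  # sampling noise only

    def test_simple_cubic_lattice_first_peak(self, spce):
        """O atoms on a cubic lattice of spacing a: first peak bin at a."""
        a, n = 3.0, 5
        grid = (np.stack(np.meshgrid(*[np.arange(n)] * 3, indexing="ij"),
                         axis=-1).reshape(-1, 3) + 0.5) * a
        coords = grid[:, None, :] + spce.atom_positions_body[None]
        frame = AAFrame(coords, spce, box=np.full(3, n * a))
        table = rdf(frame, pair="OO", dr=0.1)
        r, g = table[:, 0], table[:, 1]
        first_nonzero = r[np.nonzero(g)[0][0]]
        assert abs(first_nonzero - a) < 0.1

    def test_long_range_limit_tends_to_one(self, spce):
        frames = [ideal_gas_frame(spce, n=300, box=(20.0,) * 3, seed=9)]
        table = rdf(frames, pair="OH", dr=0.5)
        assert table[-1, 1] == pytest.approx(1.0, abs=0.15)

    def test_rmax_beyond_half_box_rejected(self, spce):
        frame = ideal_gas_frame(spce, n=10, box=(20.0,) * 3, seed=1)
        with pytest.raises(ObservableError, match="r_max"):
            rdf(frame, pair="OO", r_max=15.0)


class TestSelfDiffusion:
    def test_random_walk_recovers_analytic_d(self, spce):
        """Gaussian walk: D = s^2/(2 dt), here in 1e-9 m^2/s."""
        s, dt = 0.05, 10.0
        traj = random_walk_traj(spce, n_beads=600, step_std=s, dt=dt,
                                n_frames=400, seed=3)
        res = self_diffusion(traj)
        expected = s ** 2 / (2 * dt) * units.DIFF_TO_1E9_M2S
        assert res.value == pytest.approx(expected, rel=0.05)
        assert res.metadata["diffusive"]

    def test_frozen_configuration_gives_zero(self, spce):
        traj = random_walk_traj(spce, n_beads=10, step_std=0.0, dt=10.0,
                                n_frames=50, seed=1)
        res = self_diffusion(traj)
        assert res.value == pytest.approx(0.0, abs=1e-9)

    def test_ballistic_motion_flagged_non_diffusive(self, spce):
        traj = Trajectory(species=[spce])
        n = 20
        v = np.linspace(0.5, 1.5, n)[:, None] * np.array([1.0, 0.5, -0.2])
        box = np.full(3, 1e5)
        for i in range(100):
            traj.append(TrajectoryFrame(
                step=i, time=i * 10.0, box=box,
                positions=box / 2 + v * (i * 10.0), quats=np.tile(
                    [1.0, 0, 0, 0], (n, 1)), vels=np.zeros((n, 3)),
                angmom=np.zeros((n, 3)), images=np.zeros((n, 3), int)))
        res = self_diffusion(traj)
        assert not res.metadata["diffusive"]
        assert res.metadata["loglog_slope"] == pytest.approx(2.0, abs=0.1)


class TestViscosityGk:
    def test_ou_series_recovers_closed_form(self):
        """OU stress: mu = V A^2 tau_c / (kB T) within 10%."""
        A, tau, dt, V, T = 50.0, 200.0, 10.0, 8000.0, 298.0
        series = synthetic_stress_series(A, tau, dt, 120000, seed=5)
        res = viscosity_gk(series, V, T, dt)
        expected = (V * 1e-30) * (A * units.ATM_TO_PA) ** 2 * (tau * 1e-15) \
            / (units.KB_SI * T) * 1e3
        assert res.value == pytest.approx(expected, rel=0.10)
        assert res.units == "mPa*s"

    def test_zero_series_gives_zero(self):
        res = viscosity_gk(np.zeros((1000, 3)), 1000.0, 298.0, 10.0)
        assert res.value == 0.0

    def test_stationarity_under_concatenation(self):
        a = synthetic_stress_series(30.0, 100.0, 10.0, 60000, seed=1)
        b = synthetic_stress_series(30.0, 100.0, 10.0, 60000, seed=2)
        mu_a = viscosity_gk(a, 1000.0, 298.0, 10.0)
        mu_ab = viscosity_gk(np.vstack([a, b]), 1000.0, 298.0, 10.0)
        tol = 3 * max(mu_a.uncertainty, 0.05 * abs(mu_a.value))
        assert abs(mu_ab.value - mu_a.value) < tol

    def test_short_series_rejected(self):
        with pytest.raises(ObservableError, match="short"):
            viscosity_gk(np.zeros((5, 3)), 1000.0, 298.0, 10.0)


class TestStokesEinstein:
    def test_hand_evaluated_value(self):
        """T=298 K, mu=1 mPa*s, r=1.58 A -> 1.38e-9 m^2/s."""
        assert stokes_einstein(1.0, 298.0, 1.58) == pytest.approx(1.38,
                                                                  abs=0.01)

    def test_inverse_proportionality_in_mu(self):
        d1 = stokes_einstein(1.0, 298.0, 1.58)
        d2 = stokes_einstein(2.0, 298.0, 1.58)
        assert d2 == pytest.approx(d1 / 2.0, rel=1e-14)

    def test_product_d_mu_constant(self):
        vals = [stokes_einstein(mu, 310.0, 2.0) * mu for mu in (0.5, 1.0, 3.0)]
        assert max(vals) == pytest.approx(min(vals), rel=1e-12)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ObservableError):
            stokes_einstein(0.0, 298.0, 1.58)


class TestSurfaceTension:
    def _slab_traj(self, spce, pressure, n_frames=4, lz=90.0):
        traj = Trajectory(species=[spce])
        n = 27
        rng = np.random.default_rng(0)
        pos = rng.random((n, 3)) * np.array([30.0, 30.0, 30.0])
        pos[:, 2] += 30.0  # liquid occupies the central third of z
        for i in range(n_frames):
            traj.append(TrajectoryFrame(
                step=i, time=float(i), box=np.array([30.0, 30.0, lz]),
                positions=pos, quats=np.tile([1.0, 0, 0, 0], (n, 1)),
                vels=np.zeros((n, 3)), angmom=np.zeros((n, 3)),
                images=np.zeros((n, 3), int),
                pressure=np.array(pressure)))
        return traj

    def test_constant_tensor_arithmetic(self, spce):
        """P_zz - P_xx = dP -> gamma = L_z dP / 2 exactly."""
        dp = 100.0
        p = np.diag([0.0, 0.0, dp])
        res = surface_tension(self._slab_traj(spce, p))
        expected = 90.0 * dp / 2.0 * units.ATM_A_TO_MJ_M2
        assert res.value == pytest.approx(expected, rel=1e-12)
        assert res.units == "mJ/m^2"

    def test_isotropic_tensor_gives_zero(self, spce):
        res = surface_tension(self._slab_traj(spce, np.eye(3) * 37.0))
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_missing_vacuum_gap_rejected(self, spce):
        traj = self._slab_traj(spce, np.eye(3))
        for f in traj.frames:  # spread beads over the whole box
            f.positions = np.random.default_rng(1).random((27, 3)) * f.box
        with pytest.raises(ObservableError, match="vacuum gap"):
            surface_tension(traj)


class TestEnthalpyVaporization:
    def test_ideal_limit_is_rt(self, spce):
        """Zero intermolecular energy -> Delta H_vap = R T = 0.5925 kcal/mol
        at 298.15 K."""
        traj = _one_bead_traj(spce, n_frames=3,
                              energies={"total": 0.0})
        res = enthalpy_vaporization(traj, 298.15)
        assert res.value == pytest.approx(0.5925, abs=1e-4)

    def test_linearity_in_pair_energy(self, spce):
        t1 = _one_bead_traj(spce, n_frames=3, energies={"total": -10.0})
        t2 = _one_bead_traj(spce, n_frames=3, energies={"total": -20.0})
        rt = units.R_GAS * 298.15
        h1 = enthalpy_vaporization(t1, 298.15).value
        h2 = enthalpy_vaporization(t2, 298.15).value
        assert h2 - rt == pytest.approx(2.0 * (h1 - rt), rel=1e-12)

    def test_missing_energy_records_rejected(self, spce):
        with pytest.raises(Exception, match="energ"):
            enthalpy_vaporization(_one_bead_traj(spce, n_frames=2), 298.15)
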