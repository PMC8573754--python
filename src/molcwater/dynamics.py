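"""Rigid-body time integration for charged-bead systems.

Translation uses velocity Verlet; orientation advances the quaternion with a
self-consistent midpoint (Richardson) iteration at constant angular momentum
between torque kicks, which is what makes the large coarse-grained timestep
possible: the sphere inertia of the bead is much larger than the atomistic
one, so the fastest rotational frequencies are strongly reduced.

In ``inertia_mode="sphere"`` the rotation reference is the bead center (the
oxygen/LJ site) and the inertia is the isotropic solid-sphere tensor.  In
``inertia_mode="atomistic"`` the molecular COM is propagated, with the
point-mass inertia and torques referenced to it, mimicking a rigid
atomistic integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import units
from .forcefield import inertia_tensor
from .interactions import ForceReport, cg_single_point
from .rigid import Configuration, quat_multiply, quat_to_matrix
from .trajio import Trajectory, TrajectoryFrame

__all__ = ["RunConfig", "initialize_velocities", "nve_step", "run",
           "kinetic_energy", "kinetic_temperature", "pressure_tensor",
           "BlowupError"]

_FORCE_LIMIT = 1.0e6  # kcal/mol/A


class BlowupError(RuntimeError):
    """Integration blew up; carries the offending step and configuration."""

    def __init__(self, message, step=None, cfg=None):
        super().__init__(message)
        self.step = step
        self.cfg = cfg


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one simulation run.

    Times in fs, temperature in K, pressure in atm.  ``mass_scale``
    multiplies bead masses and inertias (>= 1); ``inertia_mode`` of None
    uses each species' own setting.
    """

    timestep: float = 10.0
    n_steps: int = 1000
    ensemble: str = "NVT"  # {NVE, NVT, NPT}
    T_target: float = 298.0
    p_target: float = 1.0
    thermostat: str = "langevin"  # {langevin, nose_hoover}
    tdamp: float = 1000.0
    pdamp: float = 5000.0
    compressibility: float = 4.5e-5  # 1/atm, Berendsen barostat input
    mass_scale: float = 1.0
    inertia_mode: str = None
    seed: int = 0
    output_every: int = 10
    r_cut: float = 10.0
    coulomb: str = "ewald"
    ewald_accuracy: float = 1e-4
    lj_shift: bool = False
    lj_tail: bool = False

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.mass_scale < 1.0:
            raise ValueError("mass_scale must be >= 1")
        if self.ensemble not in ("NVE", "NVT", "NPT"):
            raise ValueError(f"unknown ensemble {self.ensemble!r}")
        if self.thermostat not in ("langevin", "nose_hoover"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")


# ---------------------------------------------------------------------------
# per-bead rigid-body parameters
# ---------------------------------------------------------------------------

class _Bodies:
    """Mass, body-frame inertia and COM offsets per bead (mass-scaled)."""

    def __init__(self, cfg: Configuration, mass_scale: float = 1.0,
                 inertia_mode: str = None):
        n = cfg.n_beads
        self.mass = np.empty(n)
        self.I_body = np.empty((n, 3, 3))
        self.com_offset = np.zeros((n, 3))
        self.mode = np.empty(n, dtype=object)
        for si, spec in enumerate(cfg.species):
            idx = np.nonzero(cfg.species_index == si)[0]
            if len(idx) == 0:
                continue
            mode = inertia_mode or spec.inertia_mode
            if mode == "atomistic":
                tensor = inertia_tensor(spec, "atomistic", about="com")
                self.com_offset[idx] = spec.com_offset_body
            else:
                tensor = inertia_tensor(spec, "sphere")
            if np.linalg.det(tensor) <= 0:
                raise ValueError(
                    f"{spec.name}: singular inertia tensor (degenerate geometry)")
            self.mass[idx] = spec.bead_mass * mass_scale
            self.I_body[idx] = tensor * mass_scale
            self.mode[idx] = mode
        self.I_inv = np.linalg.inv(self.I_body)
        # principal decomposition, used for angular-momentum sampling/thermostat
        evals, evecs = np.linalg.eigh(self.I_body)
        self.I_princ = evals  # (n, 3)
        self.princ_axes = evecs  # (n, 3, 3), columns are principal axes

    def centers(self, cfg: Configuration) -> np.ndarray:
        """Propagation centers (bead origin, or COM in atomistic mode)."""
        rot = quat_to_matrix(cfg.q)
        return cfg.P + np.einsum("nij,nj->ni", rot, self.com_offset)

    def origin_from_center(self, X: np.ndarray, q: np.ndarray) -> np.ndarray:
        rot = quat_to_matrix(q)
        return X - np.einsum("nij,nj->ni", rot, self.com_offset)

    def center_torques(self, cfg: Configuration, report: ForceReport) -> np.ndarray:
        """Torques about the propagation centers."""
        rot = quat_to_matrix(cfg.q)
        c_lab = np.einsum("nij,nj->ni", rot, self.com_offset)
        return report.torques - np.cross(c_lab, report.forces)


# ---------------------------------------------------------------------------
# kinetic quantities
# ---------------------------------------------------------------------------

def _rot_ke_mech(cfg: Configuration, bodies: _Bodies) -> float:
    Lb = np.einsum("nji,nj->ni", quat_to_matrix(cfg.q), cfg.L)  # R^T L
    return 0.5 * float(np.einsum("ni,nij,nj->", Lb, bodies.I_inv, Lb))


def kinetic_energy(cfg: Configuration, bodies: _Bodies = None,
                   mass_scale: float = 1.0, inertia_mode: str = None):
    """(translational, rotational) kinetic energy in kcal/mol."""
    bodies = bodies or _Bodies(cfg, mass_scale, inertia_mode)
    ke_t = 0.5 * float(np.einsum("n,ni,ni->", bodies.mass, cfg.v, cfg.v))
    return ke_t * units.MVV2E, _rot_ke_mech(cfg, bodies) * units.MVV2E


def kinetic_temperature(cfg: Configuration, bodies: _Bodies = None,
                        remove_com: bool = True) -> float:
    bodies = bodies or _Bodies(cfg)
    ke_t, ke_r = kinetic_energy(cfg, bodies)
    n = cfg.n_beads
    dof = 3 * n - (3 if remove_com and n > 1 else 0) + 3 * n
    return 2.0 * (ke_t + ke_r) / (dof * units.KB)


def pressure_tensor(cfg: Configuration, report: ForceReport,
                    bodies: _Bodies = None) -> np.ndarray:
    """Molecular pressure tensor in atm: (sum m v v + W) / V."""
    bodies = bodies or _Bodies(cfg)
    kin = np.einsum("n,ni,nj->ij", bodies.mass, cfg.v, cfg.v) * units.MVV2E
    return (kin + report.virial) / cfg.volume * units.P2ATM


# ---------------------------------------------------------------------------
# velocity initialization
# ---------------------------------------------------------------------------

def initialize_velocities(cfg: Configuration, T: float, seed: int,
                          mass_scale: float = 1.0,
                          inertia_mode: str = None) -> Configuration:
    """Maxwell-Boltzmann linear velocities and angular momenta at T.

    Net linear momentum is removed and both kinetic reservoirs are rescaled
    so the instantaneous kinetic temperature matches T exactly.
    """
    if T < 0:
        raise ValueError("temperature must be non-negative")
    out = cfg.copy()
    n = cfg.n_beads
    bodies = _Bodies(cfg, mass_scale, inertia_mode)
    if T == 0:
        out.v = np.zeros((n, 3))
        out.L = np.zeros((n, 3))
        return out
    rng = np.random.default_rng(seed)
    kT = units.KB_MECH * T
    v = rng.standard_normal((n, 3)) * np.sqrt(kT / bodies.mass)[:, None]
    v -= (bodies.mass[:, None] * v).sum(axis=0) / bodies.mass.sum()
    # angular momentum in the principal body frame, then to body, then lab
    L_princ = rng.standard_normal((n, 3)) * np.sqrt(kT * bodies.I_princ)
    L_body = np.einsum("nij,nj->ni", bodies.princ_axes, L_princ)
    L = np.einsum("nij,nj->ni", quat_to_matrix(out.q), L_body)
    out.v, out.L = v, L
    ke_t, ke_r = kinetic_energy(out, bodies)
    dof_t = 3 * n - (3 if n > 1 else 0)
    if ke_t > 0:
        out.v *= math.sqrt(0.5 * dof_t * units.KB * T / ke_t)
    if ke_r > 0:
        out.L *= math.sqrt(0.5 * 3 * n * units.KB * T / ke_r)
    return out


# ---------------------------------------------------------------------------
# quaternion drift (Richardson / self-consistent midpoint)
# ---------------------------------------------------------------------------

def _qdot(q: np.ndarray, L: np.ndarray, I_inv: np.ndarray) -> np.ndarray:
    L_body = np.einsum("nji,nj->ni", quat_to_matrix(q), L)
    omega_body = np.einsum("nij,nj->ni", I_inv, L_body)
    omega_quat = np.concatenate([np.zeros((len(q), 1)), omega_body], axis=-1)
    return 0.5 * quat_multiply(q, omega_quat)


def _advance_quaternions(q, L, I_inv, dt, tol=1e-12, max_iter=60):
    q1 = q + dt * _qdot(q, L, I_inv)
    for _ in range(max_iter):
        q_mid = 0.5 * (q + q1)
        q_mid = q_mid / np.linalg.norm(q_mid, axis=-1, keepdims=True)
        q1_new = q + dt * _qdot(q_mid, L, I_inv)
        delta = np.abs(q1_new - q1).max()
        q1 = q1_new
        if delta < tol:
            break
    return q1 / np.linalg.norm(q1, axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _check_finite(report: ForceReport, cfg: Configuration, step: int):
    fmax = np.abs(report.forces).max() if report.forces.size else 0.0
    if not np.isfinite(fmax) or fmax > _FORCE_LIMIT or not np.isfinite(
            cfg.P).all():
        raise BlowupError(
            f"blow-up at step {step}: max |force| = {fmax:.3e} kcal/mol/A",
            step=step, cfg=cfg)


def nve_step(cfg: Configuration, report: ForceReport, dt: float,
             force_fn=None, bodies: _Bodies = None):
    """One velocity-Verlet step; returns (new_cfg, new_report).

    ``report`` must hold forces/torques for ``cfg``; ``force_fn`` recomputes
    them after the drift (defaults to :func:`cg_single_point` with its
    default cutoffs).
    """
    bodies = bodies or _Bodies(cfg)
    force_fn = force_fn or cg_single_point
    _check_finite(report, cfg, -1)
    half = 0.5 * dt * units.E2MVV
    out = cfg.copy()
    X = bodies.centers(cfg)
    T_c = bodies.center_torques(cfg, report)
    out.v = cfg.v + half * report.forces / bodies.mass[:, None]
    out.L = cfg.L + half * T_c
    X = X + dt * out.v
    out.q = _advance_quaternions(cfg.q, out.L, bodies.I_inv, dt)
    out.P = bodies.origin_from_center(X, out.q)
    new_report = force_fn(out)
    _check_finite(new_report, out, -1)
    out.v = out.v + half * new_report.forces / bodies.mass[:, None]
    out.L = out.L + half * bodies.center_torques(out, new_report)
    return out, new_report


class _Langevin:
    def __init__(self, T, tdamp, rng):
        self.T, self.tdamp, self.rng = T, tdamp, rng

    def apply(self, cfg, bodies, dt):
        c1 = math.exp(-dt / self.tdamp)
        c2 = math.sqrt(max(1.0 - c1 * c1, 0.0))
        kT = units.KB_MECH * self.T
        cfg.v = c1 * cfg.v + c2 * np.sqrt(kT / bodies.mass)[:, None] \
            * self.rng.standard_normal(cfg.v.shape)
        rot = quat_to_matrix(cfg.q)
        L_body = np.einsum("nji,nj->ni", rot, cfg.L)
        L_princ = np.einsum("nji,nj->ni", bodies.princ_axes, L_body)
        L_princ = c1 * L_princ + c2 * np.sqrt(kT * bodies.I_princ) \
            * self.rng.standard_normal(L_princ.shape)
        L_body = np.einsum("nij,nj->ni", bodies.princ_axes, L_princ)
        cfg.L = np.einsum("nij,nj->ni", rot, L_body)


class _NoseHoover:
    def __init__(self, T, tdamp, dof):
        self.T, self.tdamp, self.dof = T, tdamp, dof
        self.xi = 0.0
        self.Q = dof * units.KB * tdamp * tdamp  # kcal/mol * fs^2

    def half_step(self, cfg, bodies, dt):
        ke_t, ke_r = kinetic_energy(cfg, bodies)
        g = (2.0 * (ke_t + ke_r) - self.dof * units.KB * self.T) / self.Q
        self.xi += 0.5 * dt * g
        s = math.exp(-0.5 * dt * self.xi)
        cfg.v *= s
        cfg.L *= s
        ke_t, ke_r = kinetic_energy(cfg, bodies)
        g = (2.0 * (ke_t + ke_r) - self.dof * units.KB * self.T) / self.Q
        self.xi += 0.5 * dt * g


def _berendsen_scale(cfg, bodies, rep, run, dt):
    p_inst = float(np.trace(pressure_tensor(cfg, rep, bodies))) / 3.0
    mu3 = 1.0 - (dt / run.pdamp) * run.compressibility * (run.p_target - p_inst)
    mu = max(0.99, min(1.01, mu3 ** (1.0 / 3.0)))
    X = bodies.centers(cfg)
    X *= mu
    cfg.box = cfg.box * mu
    cfg.P = bodies.origin_from_center(X, cfg.q)


def run(cfg: Configuration, run_config: RunConfig) -> Trajectory:
    """Integrate ``n_steps`` and stream frames at the configured cadence.

    Frames store wrapped positions with image flags, velocities, angular
    momenta, the potential-energy decomposition, kinetic energy,
    temperature and the molecular pressure tensor.
    """
    rc = run_config
    bodies = _Bodies(cfg, rc.mass_scale, rc.inertia_mode)
    rng = np.random.default_rng(rc.seed)

    def force_fn(c):
        return cg_single_point(c, r_cut=rc.r_cut, coulomb=rc.coulomb,
                               accuracy=rc.ewald_accuracy,
                               lj_shift=rc.lj_shift, lj_tail=rc.lj_tail)

    thermo = None
    if rc.ensemble in ("NVT", "NPT"):
        n = cfg.n_beads
        dof = 3 * n - (3 if n > 1 else 0) + 3 * n
        if rc.thermostat == "langevin":
            thermo = _Langevin(rc.T_target, rc.tdamp, rng)
        else:
            thermo = _NoseHoover(rc.T_target, rc.tdamp, dof)

    state = cfg.copy()
    rep = force_fn(state)
    _check_finite(rep, state, 0)
    traj = Trajectory(species=list(cfg.species))

    def record(step, state, rep):
        pos, images = state.wrapped()
        ke_t, ke_r = kinetic_energy(state, bodies)
        energies = {
            "total": rep.energy_total, "lj": rep.energy_lj,
            "coul_real": rep.energy_coul_real,
            "coul_recip": rep.energy_coul_recip,
            "coul_self": rep.energy_coul_self,
            "kinetic": ke_t + ke_r,
            "temperature": kinetic_temperature(state, bodies),
        }
        traj.append(TrajectoryFrame(
            step=step, time=step * rc.timestep, box=state.box.copy(),
            positions=pos, quats=state.q.copy(), vels=state.v.copy(),
            angmom=state.L.copy(), images=images,
            species_index=state.species_index.copy(), energies=energies,
            pressure=pressure_tensor(state, rep, bodies)))

    record(0, state, rep)
    for step in range(1, rc.n_steps + 1):
        if isinstance(thermo, _NoseHoover):
            thermo.half_step(state, bodies, rc.timestep)
        try:
            state, rep = nve_step(state, rep, rc.timestep, force_fn, bodies)
        except BlowupError as exc:
            raise BlowupError(f"{exc} (run step {step})", step=step,
                              cfg=exc.cfg) from None
        if isinstance(thermo, _NoseHoover):
            thermo.half_step(state, bodies, rc.timestep)
        elif isinstance(thermo, _Langevin):
            thermo.apply(state, bodies, rc.timestep)
        if rc.ensemble == "NPT":
            _berendsen_scale(state, bodies, rep, rc, rc.timestep)
        if step % rc.output_every == 0 or step == rc.n_steps:
            record(step, state, rep)
    return traj
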