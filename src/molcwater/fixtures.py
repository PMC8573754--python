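"""Deterministic generators of synthetic test systems.

Everything here is reproducible bit-exactly from (parameters, seed): cubic
water lattices at a target density with random orientations, dimer scans,
rock-salt ion lattices for the Madelung check, ideal-gas frames, liquid
slabs with a vacuum gap, exponentially correlated synthetic stress series
and diffusive random-walk trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units
from .forcefield import AtomSite, WaterModelSpec, load_model
from .rigid import AAFrame, Configuration, quat_rotate, random_quaternions
from .trajio import Trajectory, TrajectoryFrame

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "cubic_lattice_water",
    "dimer_scan",
    "rocksalt",
    "ideal_gas_frame",
    "slab",
    "synthetic_stress_series",
    "random_walk_traj",
    "point_ion_species",
]


class FixtureError(ValueError):
    pass


def _resolve(model) -> WaterModelSpec:
    return model if isinstance(model, WaterModelSpec) else load_model(model)


def point_ion_species(charge: float, name: str = None,
                      mass: float = 1.0) -> WaterModelSpec:
    """A structureless charged bead (one central charge, no LJ).

    Used for lattice-electrostatics checks; deliberately skips the
    water-model neutrality invariant (system neutrality is enforced by the
    Ewald evaluator instead).
    """
    site = AtomSite(name or f"ion{charge:+g}", mass, charge, np.zeros(3))
    return WaterModelSpec(
        name=name or f"ion{charge:+g}",
        atom_sites=(site,),
        bead_mass=mass,
        bead_radius=1.0,
        charge_sites=((charge, np.zeros(3)),),
    )


def water_box_edge(n: int, density: float, bead_mass: float) -> float:
    """Edge length (A) of a cubic box of n beads at the target g/cm^3."""
    return (n * bead_mass * units.DENSITY_GCM3 / density) ** (1.0 / 3.0)


def cubic_lattice_water(model="SPC-E", n: int = 125, density: float = 0.997,
                        seed: int = 0, min_spacing_factor: float = 0.7
                        ) -> Configuration:
    """n beads on a cubic lattice at the target density, random orientations."""
    spec = _resolve(model)
    edge = water_box_edge(n, density, spec.bead_mass)
    nc = math.ceil(n ** (1.0 / 3.0))
    a = edge / nc
    idx = np.stack(np.meshgrid(*[np.arange(nc)] * 3, indexing="ij"),
                   axis=-1).reshape(-1, 3)
    # partial occupancy fills one sublattice first so few beads stay spread
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], idx.sum(axis=1) % 2))
    pts = (idx[order][:n] + 0.5) * a
    if n > 1:
        if n <= 1000:
            d = pts[:, None, :] - pts[None, :, :]
            d -= edge * np.round(d / edge)
            r = np.sqrt((d ** 2).sum(axis=-1))
            min_dist = r[~np.eye(n, dtype=bool)].min()
        else:  # dense lattice: nearest neighbors sit one cell apart
            min_dist = a
        if min_dist < min_spacing_factor * spec.bead_radius:
            raise FixtureError(
                f"lattice spacing {min_dist:.2f} A would overlap beads of "
                f"radius {spec.bead_radius:.2f} A at density {density} g/cm^3")
    rng = np.random.default_rng(seed)
    return Configuration(P=pts, q=random_quaternions(n, rng),
                         box=np.full(3, edge), species=[spec])


def dimer_scan(model="SPC-E", separations=(2.5, 3.0, 3.5, 4.0, 5.0),
               seed: int = 0, quats=None, box=None) -> list[Configuration]:
    """Two molecules at a series of O-O separations along x.

    The relative orientation (fixed across the scan) is drawn from ``seed``
    unless two quaternions are given.  Isolated (non-periodic) by default.
    """
    spec = _resolve(model)
    if quats is None:
        quats = random_quaternions(2, np.random.default_rng(seed))
    quats = np.asarray(quats, dtype=float)
    out = []
    for r in separations:
        if box is None:
            b = np.full(3, 2.0 * max(float(r), 10.0) + 100.0)
            periodic = False
        else:
            b = np.asarray(box, dtype=float)
            periodic = True
        center = b / 2.0
        P = np.array([center - [r / 2.0, 0, 0], center + [r / 2.0, 0, 0]])
        out.append(Configuration(P=P, q=quats.copy(), box=b, species=[spec],
                                 periodic=periodic))
    return out


def rocksalt(a: float = 2.82, n_cells: int = 2) -> Configuration:
    """Periodic NaCl-type lattice of +-1 e point beads.

    ``a`` is the nearest-neighbor distance; the box holds ``(2 n_cells)^3``
    ions with alternating charges.
    """
    npts = 2 * n_cells
    idx = np.stack(np.meshgrid(*[np.arange(npts)] * 3, indexing="ij"),
                   axis=-1).reshape(-1, 3)
    signs = (-1.0) ** idx.sum(axis=1)
    plus = point_ion_species(+1.0, "cation")
    minus = point_ion_species(-1.0, "anion")
    species_index = (signs < 0).astype(int)
    P = (idx + 0.5) * a
    box = np.full(3, npts * a)
    n = len(P)
    return Configuration(P=P, q=np.tile([1.0, 0, 0, 0], (n, 1)), box=box,
                         species=[plus, minus], species_index=species_index)


def ideal_gas_frame(model="SPC-E", n: int = 500, box=(30.0, 30.0, 30.0),
                    seed: int = 0) -> AAFrame:
    """Uniform random rigid molecules (no interactions applied): g(r) = 1."""
    spec = _resolve(model)
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    P = rng.random((n, 3)) * box
    quats = random_quaternions(n, rng)
    coords = np.array([P[i] + quat_rotate(quats[i], spec.atom_positions_body)
                       for i in range(n)])
    return AAFrame(coords=coords, species=spec, box=box)


def slab(model="SPC-E", n: int = 64, density: float = 0.997,
         vacuum_factor: float = 3.0, seed: int = 0) -> Configuration:
    """Liquid slab in the center of a box elongated along z by the factor."""
    cfg = cubic_lattice_water(model, n, density, seed)
    lz = cfg.box[2]
    box = cfg.box.copy()
    box[2] = lz * vacuum_factor
    P = cfg.P.copy()
    P[:, 2] += 0.5 * (box[2] - lz)
    return Configuration(P=P, q=cfg.q, box=box, species=cfg.species)


def synthetic_stress_series(amplitude: float, tau_c: float, dt: float,
                            n: int, seed: int = 0,
                            n_components: int = 3) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck series, std ``amplitude`` (atm) and
    autocorrelation amplitude^2 * exp(-t/tau_c); shape (n, n_components)."""
    rng = np.random.default_rng(seed)
    c = math.exp(-dt / tau_c)
    s = amplitude * math.sqrt(1.0 - c * c)
    x = np.empty((n, n_components))
    x[0] = amplitude * rng.standard_normal(n_components)
    noise = rng.standard_normal((n - 1, n_components))
    for i in range(1, n):
        x[i] = c * x[i - 1] + s * noise[i - 1]
    return x


def random_walk_traj(model="SPC-E", n_beads: int = 64, step_std: float = 0.1,
                     dt: float = 10.0, n_frames: int = 512,
                     seed: int = 0) -> Trajectory:
    """Gaussian random walk (per-axis step variance step_std^2): the
    Einstein relation gives D = step_std^2 / (2 dt) exactly."""
    spec = _resolve(model)
    rng = np.random.default_rng(seed)
    box = np.full(3, 1.0e4)
    x = np.cumsum(
        np.vstack([np.zeros((1, n_beads, 3)),
                   step_std * rng.standard_normal((n_frames - 1, n_beads, 3))]),
        axis=0) + box / 2.0
    traj = Trajectory(species=[spec])
    zero3 = np.zeros((n_beads, 3))
    quats = np.tile([1.0, 0, 0, 0], (n_beads, 1))
    for i in range(n_frames):
        traj.append(TrajectoryFrame(
            step=i, time=i * dt, box=box.copy(), positions=x[i],
            quats=quats.copy(), vels=zero3.copy(), angmom=zero3.copy(),
            images=np.zeros((n_beads, 3), dtype=int)))
    return traj


_KINDS = {
    "cubic_lattice_water": cubic_lattice_water,
    "dimer_scan": dimer_scan,
    "rocksalt": rocksalt,
    "ideal_gas": ideal_gas_frame,
    "slab": slab,
    "synthetic_stress_series": synthetic_stress_series,
    "random_walk_traj": random_walk_traj,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture: kind + per-kind parameters + seed."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def make_fixture(spec: FixtureSpec):
    if spec.kind not in _KINDS:
        raise FixtureError(f"unknown fixture kind {spec.kind!r}; "
                           f"choose from {sorted(_KINDS)}")
    fn = _KINDS[spec.kind]
    kwargs = dict(spec.params)
    if spec.kind not in ("rocksalt",):
        kwargs.setdefault("seed", spec.seed)
    return fn(**kwargs)
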