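"""Quaternion algebra, bead states and AA<->CG mapping.

Quaternions are scalar-first and encode the body->lab rotation of each bead.
The lab-frame position of every virtual charge is reconstructed on demand as
R_i = P + q * S_i * q^-1 (never integrated independently), where S_i is the
body-frame offset stored in the force-field spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .forcefield import WaterModelSpec

__all__ = [
    "quat_rotate",
    "quat_multiply",
    "quat_conjugate",
    "quat_to_matrix",
    "random_quaternions",
    "canonical_quaternion",
    "BeadState",
    "Configuration",
    "AAFrame",
    "site_positions",
    "map_to_cg",
    "reverse_map",
    "MappingError",
]

_UNIT_TOL = 1e-9


class MappingError(ValueError):
    """Atomistic geometry inconsistent with the rigid template."""


# ---------------------------------------------------------------------------
# quaternion kernels (scalar-first, body->lab)
# ---------------------------------------------------------------------------

def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b, scalar-first; broadcasts over leading axes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(a, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix R with R @ u_body = lab vector; (..., 3, 3)."""
    q = np.asarray(q, dtype=float)
    w, x, y, z = np.moveaxis(q, -1, 0)
    row0 = np.stack(
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1
    )
    row1 = np.stack(
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1
    )
    row2 = np.stack(
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1
    )
    return np.stack([row0, row1, row2], axis=-2)


def quat_rotate(q: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Rotate body-frame vector(s) u into the lab frame.

    Raises if the quaternion norm deviates from 1 beyond tolerance.
    """
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(norm - 1.0) > 1e-6):
        raise ValueError("non-unit quaternion passed to quat_rotate")
    if q.ndim == 1:
        return np.asarray(u, dtype=float) @ quat_to_matrix(q).T
    return np.einsum("...ij,...j->...i", quat_to_matrix(q), np.asarray(u, dtype=float))


def canonical_quaternion(q: np.ndarray) -> np.ndarray:
    """Resolve the q = -q ambiguity: make the scalar part non-negative."""
    q = np.asarray(q, dtype=float)
    sign = np.where(q[..., :1] < 0, -1.0, 1.0)
    return q * sign


def random_quaternions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform unit quaternions on S^3 (Shoemake subgroup algorithm)."""
    u1, u2, u3 = rng.random((3, n))
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    return np.stack(
        [
            a * np.sin(2 * np.pi * u2),
            a * np.cos(2 * np.pi * u2),
            b * np.sin(2 * np.pi * u3),
            b * np.cos(2 * np.pi * u3),
        ],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# states and configurations
# ---------------------------------------------------------------------------

@dataclass
class BeadState:
    """One rigid bead: position, orientation, velocity, angular momentum."""

    P: np.ndarray  # (3,) A, lab frame
    q: np.ndarray  # (4,) unit quaternion, scalar-first, body->lab
    v: np.ndarray = None  # (3,) A/fs
    L: np.ndarray = None  # (3,) g/mol*A^2/fs, lab frame
    species: WaterModelSpec = None

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if abs(np.linalg.norm(self.q) - 1.0) > _UNIT_TOL:
            raise ValueError("bead quaternion is not unit-norm")
        self.v = np.zeros(3) if self.v is None else np.asarray(self.v, dtype=float)
        self.L = np.zeros(3) if self.L is None else np.asarray(self.L, dtype=float)


@dataclass
class Configuration:
    """A set of rigid beads in an orthorhombic (optionally periodic) box.

    Arrays are stored stacked for vectorized evaluation; ``states`` exposes
    the per-bead view.  ``species_index`` maps each bead to an entry of
    ``species`` (pure-water systems have a single entry).
    """

    P: np.ndarray  # (N, 3)
    q: np.ndarray  # (N, 4)
    box: np.ndarray  # (3,) edge lengths, A
    species: list  # list[WaterModelSpec]
    species_index: np.ndarray = None  # (N,) int
    v: np.ndarray = None  # (N, 3)
    L: np.ndarray = None  # (N, 3)
    periodic: bool = True

    def __post_init__(self):
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        self.box = np.asarray(self.box, dtype=float)
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if not isinstance(self.species, (list, tuple)):
            self.species = [self.species]
        self.species = list(self.species)
        n = len(self.P)
        if self.species_index is None:
            self.species_index = np.zeros(n, dtype=int)
        else:
            self.species_index = np.asarray(self.species_index, dtype=int)
        self.v = np.zeros((n, 3)) if self.v is None else np.asarray(self.v, dtype=float)
        self.L = np.zeros((n, 3)) if self.L is None else np.asarray(self.L, dtype=float)
        norms = np.linalg.norm(self.q, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("configuration contains non-unit quaternions")
        self.q = self.q / norms[:, None]

    @property
    def n_beads(self) -> int:
        return len(self.P)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def states(self) -> list[BeadState]:
        return [
            BeadState(self.P[i], self.q[i], self.v[i], self.L[i],
                      self.species[self.species_index[i]])
            for i in range(self.n_beads)
        ]

    @classmethod
    def from_states(cls, states: list[BeadState], box, periodic: bool = True):
        species, index = [], []
        for s in states:
            if s.species not in species:
                species.append(s.species)
            index.append(species.index(s.species))
        return cls(
            P=np.array([s.P for s in states]),
            q=np.array([s.q for s in states]),
            v=np.array([s.v for s in states]),
            L=np.array([s.L for s in states]),
            box=box,
            species=species,
            species_index=np.array(index),
            periodic=periodic,
        )

    def wrapped(self) -> tuple[np.ndarray, np.ndarray]:
        """Positions wrapped to [0, box) plus the integer image flags."""
        images = np.floor(self.P / self.box).astype(int)
        return self.P - images * self.box, images

    def copy(self) -> "Configuration":
        return Configuration(
            P=self.P.copy(), q=self.q.copy(), box=self.box.copy(),
            species=list(self.species), species_index=self.species_index.copy(),
            v=self.v.copy(), L=self.L.copy(), periodic=self.periodic,
        )


@dataclass
class AAFrame:
    """Atomistic coordinates of rigid molecules, ordered like the spec sites.

    ``coords`` has shape (n_molecules, n_atom_sites, 3) in lab-frame A.
    """

    coords: np.ndarray
    species: WaterModelSpec
    box: np.ndarray = None
    periodic: bool = True

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        n_sites = len(self.species.atom_sites)
        if self.coords.shape[1] != n_sites:
            raise MappingError(
                f"frame has {self.coords.shape[1]} atoms per molecule, "
                f"model {self.species.name} has {n_sites}"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_molecules(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# site reconstruction and mapping
# ---------------------------------------------------------------------------

def site_positions(state: BeadState) -> np.ndarray:
    """Lab-frame virtual-charge positions R_i = P + rot(q, S_i)."""
    return state.P + quat_rotate(state.q, state.species.charge_offsets)


def all_site_positions(cfg: Configuration, offsets: np.ndarray) -> np.ndarray:
    """(N, n_sites, 3) lab positions of per-bead body offsets (vectorized)."""
    rot = quat_to_matrix(cfg.q)  # (N, 3, 3)
    return cfg.P[:, None, :] + np.einsum("nij,sj->nsi", rot, offsets)


def map_to_cg(aa: AAFrame, spec: WaterModelSpec = None, tol: float = 1e-3,
              box=None) -> Configuration:
    """Fit bead position and quaternion to each rigid molecule.

    The bead center is placed on the oxygen/LJ site and the orientation is
    the orthogonal-Procrustes rotation taking the body-frame site template to
    the observed sites (exact for exactly rigid molecules).  Raises
    MappingError if any molecule deviates from the rigid template by more
    than ``tol`` A.
    """
    spec = spec or aa.species
    template = spec.atom_positions_body
    lj_idx = spec.atom_sites.index(spec.lj_site)
    n = aa.n_molecules
    P = aa.coords[:, lj_idx, :].copy()
    quats = np.empty((n, 4))
    for i in range(n):
        rel = aa.coords[i] - P[i]
        rot, _ = Rotation.align_vectors(rel, template)
        quats[i] = rot.as_quat(scalar_first=True)
        resid = np.abs(rel - rot.apply(template)).max()
        if resid > tol:
            raise MappingError(
                f"molecule {i} deviates from the rigid {spec.name} template "
                f"by {resid:.2e} A (tol {tol:g})"
            )
    box = aa.box if box is None else box
    if box is None:
        # isolated cluster: enclose generously
        span = aa.coords.reshape(-1, 3)
        box = np.full(3, float(span.max() - span.min()) + 100.0)
        periodic = False
    else:
        periodic = aa.periodic
    return Configuration(P=P, q=quats, box=box, species=[spec], periodic=periodic)


def reverse_map(cfg: Configuration) -> AAFrame:
    """Rebuild atomistic coordinates from bead positions and quaternions.

    Only single-species configurations map to a single AAFrame.
    """
    if len(cfg.species) != 1:
        raise MappingError("reverse_map requires a single-species configuration")
    spec = cfg.species[0]
    coords = all_site_positions(cfg, spec.atom_positions_body)
    return AAFrame(coords=coords, species=spec,
                   box=cfg.box if cfg.periodic else None, periodic=cfg.periodic)
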