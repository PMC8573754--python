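"""Energies, forces and torques for beads decorated with off-center charges.

The Coulomb energy between two virtual charges is the plain pair potential
U = C q1 q2 / |R1 - R2| with R_i = P_i + rot(q_i, S_i).  Because R_i depends
on the parent bead position only through a translation, the force on the
parent bead equals the force on the virtual charge, F2 = -F1, and each
charge additionally exerts the torque (R_i - P_i) x F_i about its bead
center.  Short-range repulsion/dispersion is a 12-6 Lennard-Jones between
bead centers (the sphere-sphere limit of the generalized Gay-Berne
potential), and periodic electrostatics use a classic Ewald split over the
virtual sites with rigid intra-bead exclusions.

All evaluators return a :class:`ForceReport` with the energy decomposition,
per-bead forces/torques and the molecular virial tensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc, erf

from . import units
from .forcefield import WaterModelSpec
from .rigid import AAFrame, BeadState, Configuration, all_site_positions, site_positions

__all__ = [
    "PairChargeResult",
    "ForceReport",
    "coulomb_pair",
    "lj_pair",
    "ewald_eval",
    "cg_single_point",
    "aa_single_point",
    "EwaldParams",
]


class InteractionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class PairChargeResult:
    """Energy, bead forces and bead torques of one virtual-charge pair."""

    energy: float  # kcal/mol
    F1: np.ndarray  # kcal/mol/A, force on parent bead 1
    F2: np.ndarray  # = -F1 exactly
    T1: np.ndarray  # kcal/mol, torque about bead center 1
    T2: np.ndarray


@dataclass
class ForceReport:
    """Total energy decomposition plus per-bead forces, torques and virial.

    ``energy_coul_self`` bundles the Ewald self term and the rigid
    intra-bead exclusion correction.  ``virial`` is the molecular virial
    tensor W (kcal/mol) referenced to bead centers, so the pressure tensor
    is (sum_i m_i v_a v_b + W_ab) / V.
    """

    n_beads: int
    energy_lj: float = 0.0
    energy_coul_real: float = 0.0
    energy_coul_recip: float = 0.0
    energy_coul_self: float = 0.0
    forces: np.ndarray = None  # (N, 3) kcal/mol/A
    torques: np.ndarray = None  # (N, 3) kcal/mol
    virial: np.ndarray = None  # (3, 3) kcal/mol

    def __post_init__(self):
        if self.forces is None:
            self.forces = np.zeros((self.n_beads, 3))
        if self.torques is None:
            self.torques = np.zeros((self.n_beads, 3))
        if self.virial is None:
            self.virial = np.zeros((3, 3))

    @property
    def energy_coul(self) -> float:
        return self.energy_coul_real + self.energy_coul_recip + self.energy_coul_self

    @property
    def energy_total(self) -> float:
        return self.energy_lj + self.energy_coul

    def __iadd__(self, other: "ForceReport") -> "ForceReport":
        self.energy_lj += other.energy_lj
        self.energy_coul_real += other.energy_coul_real
        self.energy_coul_recip += other.energy_coul_recip
        self.energy_coul_self += other.energy_coul_self
        self.forces += other.forces
        self.torques += other.torques
        self.virial += other.virial
        return self


# ---------------------------------------------------------------------------
# elementary pair interactions
# ---------------------------------------------------------------------------

def coulomb_pair(q1: float, q2: float, state1: BeadState, site1: int,
                 state2: BeadState, site2: int) -> PairChargeResult:
    """Coulomb interaction of two off-center charges, mapped to their beads."""
    R1 = site_positions(state1)[site1]
    R2 = site_positions(state2)[site2]
    d = R1 - R2
    r = np.linalg.norm(d)
    if r < 1e-12:
        raise InteractionError("coincident virtual charges (Coulomb singularity)")
    energy = units.COULOMB * q1 * q2 / r
    F1 = units.COULOMB * q1 * q2 * d / r**3
    F2 = -F1
    T1 = np.cross(R1 - state1.P, F1)
    T2 = np.cross(R2 - state2.P, F2)
    return PairChargeResult(energy=float(energy), F1=F1, F2=F2, T1=T1, T2=T2)


def lj_pair(r: float, sigma: float, epsilon: float, cutoff: float,
            shift: bool = False) -> tuple[float, float]:
    """12-6 Lennard-Jones energy and scalar force magnitude -dE/dr.

    Truncated at ``cutoff`` (energy optionally shifted to zero there).
    """
    if r <= 0:
        raise InteractionError("non-positive LJ distance")
    if r >= cutoff:
        return 0.0, 0.0
    sr6 = (sigma / r) ** 6
    e = 4.0 * epsilon * (sr6 * sr6 - sr6)
    if shift:
        sc6 = (sigma / cutoff) ** 6
        e -= 4.0 * epsilon * (sc6 * sc6 - sc6)
    f = 24.0 * epsilon * (2.0 * sr6 * sr6 - sr6) / r
    return float(e), float(f)


# ---------------------------------------------------------------------------
# Ewald parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EwaldParams:
    """Splitting parameter and k-space cutoff from a target relative accuracy.

    Standard heuristics (erfc(alpha r_cut) ~ accuracy, truncation of the
    reciprocal sum at the matching Gaussian width) bound the error of a
    single pair; a fixed margin of +1 on sqrt(-ln accuracy) absorbs the
    summation over many pairs, so the total energy is stable against the
    choice of alpha to within ``accuracy`` (relative).
    """

    alpha: float  # 1/A
    k_cut: float  # 1/A
    r_cut: float  # A
    accuracy: float

    _MARGIN = 1.0

    @classmethod
    def from_accuracy(cls, accuracy: float, r_cut: float,
                      alpha: float = None) -> "EwaldParams":
        s = math.sqrt(max(-math.log(accuracy), 1.0)) + cls._MARGIN
        if alpha is None:
            alpha = s / r_cut
        return cls(alpha=alpha, k_cut=2.0 * alpha * s, r_cut=r_cut,
                   accuracy=accuracy)


_KTABLE_CACHE: dict = {}


def _k_table(box: np.ndarray, k_cut: float):
    """Half-space reciprocal vectors with |k| <= k_cut (k=0 excluded),
    together with their integer indices; cached per (box, k_cut)."""
    key = (round(float(box[0]), 12), round(float(box[1]), 12),
           round(float(box[2]), 12), round(float(k_cut), 12))
    hit = _KTABLE_CACHE.get(key)
    if hit is not None:
        return hit
    nmax = np.ceil(k_cut * box / (2.0 * np.pi)).astype(int)
    nx = np.arange(0, nmax[0] + 1)
    ny = np.arange(-nmax[1], nmax[1] + 1)
    nz = np.arange(-nmax[2], nmax[2] + 1)
    gx, gy, gz = np.meshgrid(nx, ny, nz, indexing="ij")
    n = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=-1)
    half = (n[:, 0] > 0) | ((n[:, 0] == 0) & (n[:, 1] > 0)) | (
        (n[:, 0] == 0) & (n[:, 1] == 0) & (n[:, 2] > 0)
    )
    n = n[half]
    k = 2.0 * np.pi * n / box
    keep = np.einsum("ij,ij->i", k, k) <= k_cut * k_cut
    result = (k[keep], n[keep], nmax)
    if len(_KTABLE_CACHE) > 32:
        _KTABLE_CACHE.clear()
    _KTABLE_CACHE[key] = result
    return result


def _k_vectors(box: np.ndarray, k_cut: float) -> np.ndarray:
    return _k_table(box, k_cut)[0]


# ---------------------------------------------------------------------------
# site-system assembly
# ---------------------------------------------------------------------------

@dataclass
class _SiteSystem:
    """Flattened charged sites + LJ sites of a configuration or AA frame."""

    centers: np.ndarray  # (N, 3) bead/torque reference centers
    site_pos: np.ndarray  # (M, 3)
    site_q: np.ndarray  # (M,)
    site_group: np.ndarray  # (M,) parent bead index
    lj_pos: np.ndarray  # (N, 3) LJ site positions (NaN rows = no LJ)
    lj_sigma: np.ndarray  # (N,)
    lj_eps: np.ndarray  # (N,)
    box: np.ndarray
    periodic: bool


def _lj_of(spec: WaterModelSpec):
    for s in spec.atom_sites:
        if s.has_lj:
            return s
    return None


def _system_from_cfg(cfg: Configuration) -> _SiteSystem:
    pos_list, q_list, g_list = [], [], []
    n = cfg.n_beads
    lj_pos = np.zeros((n, 3))
    lj_sigma = np.zeros(n)
    lj_eps = np.zeros(n)
    for si, spec in enumerate(cfg.species):
        mask = cfg.species_index == si
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            continue
        sub = Configuration(P=cfg.P[idx], q=cfg.q[idx], box=cfg.box,
                            species=[spec], periodic=cfg.periodic)
        if len(spec.charge_sites) > 0:
            sites = all_site_positions(sub, spec.charge_offsets)  # (n_i, ns, 3)
            ns = sites.shape[1]
            pos_list.append(sites.reshape(-1, 3))
            q_list.append(np.tile(spec.charges, len(idx)))
            g_list.append(np.repeat(idx, ns))
        ljs = _lj_of(spec)
        if ljs is not None:
            lj_pos[idx] = all_site_positions(sub, ljs.position_body[None])[:, 0, :]
            lj_sigma[idx] = ljs.lj_sigma
            lj_eps[idx] = ljs.lj_epsilon
        else:
            lj_pos[idx] = cfg.P[idx]
    site_pos = np.concatenate(pos_list) if pos_list else np.zeros((0, 3))
    site_q = np.concatenate(q_list) if q_list else np.zeros(0)
    site_group = np.concatenate(g_list).astype(int) if g_list else np.zeros(0, int)
    return _SiteSystem(cfg.P.copy(), site_pos, site_q, site_group,
                       lj_pos, lj_sigma, lj_eps, cfg.box.copy(), cfg.periodic)


def _system_from_aa(aa: AAFrame, box=None) -> _SiteSystem:
    spec = aa.species
    n = aa.n_molecules
    charged = [i for i, s in enumerate(spec.atom_sites) if s.charge != 0.0]
    site_pos = aa.coords[:, charged, :].reshape(-1, 3)
    site_q = np.tile([spec.atom_sites[i].charge for i in charged], n)
    site_group = np.repeat(np.arange(n), len(charged))
    ljs = _lj_of(spec)
    lj_idx = spec.atom_sites.index(ljs)
    lj_pos = aa.coords[:, lj_idx, :]
    masses = np.array([s.mass for s in spec.atom_sites])
    centers = (masses[None, :, None] * aa.coords).sum(axis=1) / masses.sum()
    box = aa.box if box is None else np.asarray(box, float)
    periodic = aa.periodic and box is not None
    if box is None:
        span = aa.coords.reshape(-1, 3)
        box = np.full(3, float(span.max() - span.min()) + 100.0)
    return _SiteSystem(centers, site_pos, site_q, site_group, lj_pos,
                       np.full(n, ljs.lj_sigma), np.full(n, ljs.lj_epsilon),
                       box, periodic)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _scatter_forces(n, ii, jj, fvec):
    F = np.empty((n, 3))
    for d in range(3):
        F[:, d] = (np.bincount(ii, weights=fvec[:, d], minlength=n)
                   - np.bincount(jj, weights=fvec[:, d], minlength=n))
    return F


class _Neighbors:
    """Bead-level pair pruning shared by the LJ and real-space Coulomb sums.

    Bead pairs are selected by the minimum-image distance of their LJ-site
    positions within ``r_cut + 2 * max site offset`` (a site pair can be in
    range only if its parent beads are); site pairs then apply their own
    minimum image, so the pruning changes nothing.
    """

    def __init__(self, sys: _SiteSystem, r_cut):
        self.sys = sys
        n = len(sys.centers)
        base = sys.lj_pos
        off = 0.0
        if len(sys.site_pos):
            d_site = sys.site_pos - base[sys.site_group]
            off = float(np.sqrt((d_site ** 2).sum(axis=-1)).max())
        ii, jj = np.triu_indices(n, k=1)
        d = base[ii] - base[jj]
        if sys.periodic:
            d = _min_image(d, sys.box)
        r2 = np.einsum("ij,ij->i", d, d)
        if r_cut is not None:
            pad = r_cut + 2.0 * off
            keep = r2 < pad * pad
            ii, jj, d, r2 = ii[keep], jj[keep], d[keep], r2[keep]
        self.ii, self.jj, self.d, self.r = ii, jj, d, np.sqrt(r2)


def _lj_eval(sys: _SiteSystem, nb: _Neighbors, r_cut, shift):
    out = {"e": 0.0, "F": np.zeros_like(sys.lj_pos), "W": np.zeros((3, 3))}
    keep = (sys.lj_eps[nb.ii] * sys.lj_eps[nb.jj] > 0) & (nb.r < r_cut)
    if not keep.any():
        return out
    ii, jj, d, r = nb.ii[keep], nb.jj[keep], nb.d[keep], nb.r[keep]
    sig = 0.5 * (sys.lj_sigma[ii] + sys.lj_sigma[jj])
    eps = np.sqrt(sys.lj_eps[ii] * sys.lj_eps[jj])
    sr6 = (sig / r) ** 6
    e = 4.0 * eps * (sr6 * sr6 - sr6)
    if shift:
        sc6 = (sig / r_cut) ** 6
        e -= 4.0 * eps * (sc6 * sc6 - sc6)
    fmag_over_r = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / (r * r)
    fvec = fmag_over_r[:, None] * d  # force on i
    out["e"] = float(e.sum())
    out["F"] = _scatter_forces(len(sys.lj_pos), ii, jj, fvec)
    out["W"] = d.T @ fvec
    return out


def _expand_site_pairs(sys: _SiteSystem, nb: _Neighbors, r_cut):
    """Site-pair table (indices, min-image separations) for inter-bead
    charged-site pairs within ``r_cut`` (None: all surviving pairs)."""
    m = len(sys.site_q)
    if m == 0 or len(nb.ii) == 0:
        z = np.zeros(0, int)
        return z, z, np.zeros((0, 3)), np.zeros(0)
    ns = m // len(sys.centers)
    uniform = (ns * len(sys.centers) == m
               and np.array_equal(sys.site_group,
                                  np.repeat(np.arange(len(sys.centers)), ns)))
    if uniform:
        a1, a2 = np.meshgrid(np.arange(ns), np.arange(ns), indexing="ij")
        s1 = (nb.ii[:, None] * ns + a1.ravel()[None, :]).reshape(-1)
        s2 = (nb.jj[:, None] * ns + a2.ravel()[None, :]).reshape(-1)
    else:
        # group site indices per bead (species with unequal site counts)
        per_bead = [np.nonzero(sys.site_group == b)[0]
                    for b in range(len(sys.centers))]
        s1_l, s2_l = [], []
        for i, j in zip(nb.ii, nb.jj):
            gi, gj = per_bead[i], per_bead[j]
            s1_l.append(np.repeat(gi, len(gj)))
            s2_l.append(np.tile(gj, len(gi)))
        s1 = np.concatenate(s1_l) if s1_l else np.zeros(0, int)
        s2 = np.concatenate(s2_l) if s2_l else np.zeros(0, int)
    d = sys.site_pos[s1] - sys.site_pos[s2]
    if sys.periodic:
        d = _min_image(d, sys.box)
    r2 = np.einsum("ij,ij->i", d, d)
    if r_cut is not None:
        keep = r2 < r_cut * r_cut
        s1, s2, d, r2 = s1[keep], s2[keep], d[keep], r2[keep]
    return s1, s2, d, np.sqrt(r2)


def _lj_tail(sys: _SiteSystem, r_cut):
    """Standard long-range corrections for the truncated LJ potential:
    isotropic energy and virial terms assuming g(r) = 1 beyond the cutoff."""
    V = float(np.prod(sys.box))
    active = np.nonzero(sys.lj_eps > 0)[0]
    e_tail = 0.0
    p_tail = 0.0  # kcal/mol/A^3
    specs = {}
    for i in active:
        key = (sys.lj_sigma[i], sys.lj_eps[i])
        specs[key] = specs.get(key, 0) + 1
    for (sa, ea), na in specs.items():
        for (sb, eb), nbn in specs.items():
            sig = 0.5 * (sa + sb)
            eps = math.sqrt(ea * eb)
            x3 = (sig / r_cut) ** 3
            x9 = x3 ** 3
            pref = (8.0 * math.pi / 3.0) * na * nbn * eps * sig ** 3 / V
            e_tail += pref * (x9 / 3.0 - x3)
            p_tail += (2.0 * pref / V) * (2.0 * x9 / 3.0 - x3)
    return e_tail, p_tail


def _coulomb_real(sys: _SiteSystem, nb: _Neighbors, r_cut, alpha=None):
    """erfc-damped (alpha given) or bare (alpha None) real-space sum over
    inter-bead site pairs."""
    e = 0.0
    F = np.zeros_like(sys.site_pos)
    W = np.zeros((3, 3))
    ii, jj, d, r = _expand_site_pairs(sys, nb, r_cut)
    if len(ii) == 0:
        return e, F, W
    if np.any(r < 1e-10):
        raise InteractionError("coincident virtual charges (Coulomb singularity)")
    qq = units.COULOMB * sys.site_q[ii] * sys.site_q[jj]
    if alpha is None:
        e_pair = qq / r
        fmag_over_r = qq / (r * r * r)
    else:
        ar = alpha * r
        ec = erfc(ar)
        e_pair = qq * ec / r
        fmag_over_r = qq * (ec / r + 2.0 * alpha / units.SQRT_PI * np.exp(-ar * ar)) / (r * r)
    fvec = fmag_over_r[:, None] * d
    return float(e_pair.sum()), _scatter_forces(len(F), ii, jj, fvec), d.T @ fvec


try:
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _recip_kernel(kvecs, A, ax0, ax1, ax2, n0, n1, n2, q, inv4a2):
        nk = kvecs.shape[0]
        m = q.shape[0]
        eikr = np.empty((nk, m), dtype=np.complex128)
        S = np.empty(nk, dtype=np.complex128)
        for kk in range(nk):
            s = 0.0 + 0.0j
            for i in range(m):
                e = ax0[i, n0[kk]] * ax1[i, n1[kk]] * ax2[i, n2[kk]]
                eikr[kk, i] = e
                s += q[i] * e
            S[kk] = s
        e_tot = 0.0
        F = np.zeros((m, 3))
        W = np.zeros((3, 3))
        for kk in range(nk):
            a = A[kk]
            s2 = (S[kk] * np.conj(S[kk])).real
            e_tot += a * s2
            k2 = (kvecs[kk, 0] ** 2 + kvecs[kk, 1] ** 2 + kvecs[kk, 2] ** 2)
            coef = 2.0 * (1.0 / k2 + inv4a2)
            fac = a * s2
            for x in range(3):
                W[x, x] += fac
                for y in range(3):
                    W[x, y] -= fac * coef * kvecs[kk, x] * kvecs[kk, y]
            t = a * np.conj(S[kk])
            for i in range(m):
                im = (eikr[kk, i] * t).imag
                c = 2.0 * q[i] * im
                F[i, 0] += c * kvecs[kk, 0]
                F[i, 1] += c * kvecs[kk, 1]
                F[i, 2] += c * kvecs[kk, 2]
        return e_tot, F, W

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False


def _coulomb_recip(sys: _SiteSystem, params: EwaldParams):
    kvecs, nidx, nmax = _k_table(sys.box, params.k_cut)
    if _HAVE_NUMBA and len(kvecs) * max(len(sys.site_q), 1) > 20000:
        V = float(np.prod(sys.box))
        k2 = np.einsum("ij,ij->i", kvecs, kvecs)
        A = (4.0 * np.pi * units.COULOMB / V) * np.exp(
            -k2 / (4.0 * params.alpha ** 2)) / k2
        tpi = 2.0 * np.pi / sys.box
        ax = [np.exp(1j * np.outer(sys.site_pos[:, d] * tpi[d],
                                   np.arange(-nmax[d], nmax[d] + 1)))
              for d in range(3)]
        e, F, W = _recip_kernel(
            kvecs, A, ax[0], ax[1], ax[2],
            (nidx[:, 0] + nmax[0]).astype(np.int64),
            (nidx[:, 1] + nmax[1]).astype(np.int64),
            (nidx[:, 2] + nmax[2]).astype(np.int64),
            sys.site_q.astype(np.float64),
            1.0 / (4.0 * params.alpha ** 2))
        return float(e), F, W
    return _coulomb_recip_numpy(sys, params)


def _coulomb_recip_numpy(sys: _SiteSystem, params: EwaldParams):
    kvecs, nidx, nmax = _k_table(sys.box, params.k_cut)
    V = float(np.prod(sys.box))
    k2 = np.einsum("ij,ij->i", kvecs, kvecs)
    A = (4.0 * np.pi * units.COULOMB / V) * np.exp(-k2 / (4.0 * params.alpha**2)) / k2
    # e^{ik.r} assembled from per-axis exponential tables (cheaper than
    # evaluating M x nk trigonometric phases directly)
    tpi = 2.0 * np.pi / sys.box
    ax = [np.exp(1j * np.outer(sys.site_pos[:, d] * tpi[d],
                               np.arange(-nmax[d], nmax[d] + 1)))
          for d in range(3)]
    eikr = ax[0][:, nidx[:, 0] + nmax[0]].copy()
    eikr *= ax[1][:, nidx[:, 1] + nmax[1]]
    eikr *= ax[2][:, nidx[:, 2] + nmax[2]]  # (M, nk)
    S = sys.site_q @ eikr
    S2 = (S * S.conj()).real
    e = float((A * S2).sum())
    T = eikr * (A * S.conj())[None, :]
    F = 2.0 * sys.site_q[:, None] * (T.imag @ kvecs)
    fac = A * S2
    coef = 2.0 * (1.0 / k2 + 1.0 / (4.0 * params.alpha**2))
    W = np.eye(3) * fac.sum() - np.einsum("k,ki,kj->ij", fac * coef, kvecs, kvecs)
    return e, F, W


def _coulomb_self_intra(sys: _SiteSystem, alpha: float):
    """Ewald self term plus the rigid intra-bead exclusion correction.

    The correction removes the erf-screened interaction the reciprocal sum
    introduces between charges of the same bead.  Its pair forces are
    central, so they cancel in the parent-bead force and torque; they are
    kept for the virial.
    """
    e_self = -units.COULOMB * alpha / units.SQRT_PI * float((sys.site_q**2).sum())
    e_intra = 0.0
    F = np.zeros_like(sys.site_pos)
    W = np.zeros((3, 3))
    order = np.argsort(sys.site_group, kind="stable")
    groups = sys.site_group[order]
    # pairs within each bead (site counts are tiny: <= 3 per bead)
    uniq, starts = np.unique(groups, return_index=True)
    bounds = list(starts) + [len(groups)]
    ii_list, jj_list = [], []
    for b in range(len(uniq)):
        members = order[bounds[b]:bounds[b + 1]]
        for a in range(len(members)):
            for c in range(a + 1, len(members)):
                ii_list.append(members[a])
                jj_list.append(members[c])
    if ii_list:
        ii = np.array(ii_list)
        jj = np.array(jj_list)
        d = sys.site_pos[ii] - sys.site_pos[jj]
        r = np.linalg.norm(d, axis=-1)
        qq = units.COULOMB * sys.site_q[ii] * sys.site_q[jj]
        ar = alpha * r
        e_intra = float((-qq * erf(ar) / r).sum())
        # force on i from U = -C qq erf(ar)/r
        fmag_over_r = qq * (2.0 * alpha / units.SQRT_PI * np.exp(-ar * ar) / r
                            - erf(ar) / (r * r)) / r
        fvec = fmag_over_r[:, None] * d
        np.add.at(F, ii, fvec)
        np.add.at(F, jj, -fvec)
        W = np.einsum("pi,pj->ij", d, fvec)
    return e_self + e_intra, F, W


# ---------------------------------------------------------------------------
# assembly of full single-point reports
# ---------------------------------------------------------------------------

def _accumulate(sys: _SiteSystem, report: ForceReport, site_F: np.ndarray,
                lj_F: np.ndarray) -> None:
    """Map site forces onto parent beads: force sum + lever-arm torques,
    and convert the atomic virial to the molecular (bead-centered) one."""
    np.add.at(report.forces, sys.site_group, site_F)
    lever = sys.site_pos - sys.centers[sys.site_group]
    np.add.at(report.torques, sys.site_group, np.cross(lever, site_F))
    report.virial -= np.einsum("pi,pj->ij", site_F, lever)
    report.forces += lj_F
    lj_lever = sys.lj_pos - sys.centers
    report.torques += np.cross(lj_lever, lj_F)
    report.virial -= np.einsum("pi,pj->ij", lj_F, lj_lever)


def _single_point(sys: _SiteSystem, r_cut, coulomb, accuracy, lj_shift,
                  alpha, lj_tail=False) -> ForceReport:
    n = len(sys.centers)
    report = ForceReport(n_beads=n)
    nb = _Neighbors(sys, r_cut if sys.periodic else None)
    lj = _lj_eval(sys, nb, r_cut if sys.periodic else 1e9, lj_shift)
    report.energy_lj = lj["e"]
    report.virial += lj["W"]
    if lj_tail and sys.periodic:
        e_tail, p_tail = _lj_tail(sys, r_cut)
        report.energy_lj += e_tail
        report.virial += p_tail * float(np.prod(sys.box)) * np.eye(3)
    site_F = np.zeros_like(sys.site_pos)
    if coulomb == "none" or len(sys.site_q) == 0:
        _accumulate(sys, report, site_F, lj["F"])
        return report
    if coulomb == "direct" or not sys.periodic:
        cut = r_cut if sys.periodic else None
        e, F, W = _coulomb_real(sys, nb, cut, alpha=None)
        report.energy_coul_real = e
        report.virial += W
        site_F = F
    elif coulomb == "ewald":
        net = float(sys.site_q.sum())
        if abs(net) > 1e-8:
            raise InteractionError(f"Ewald requires a neutral system (net {net:g} e)")
        if 2.0 * r_cut > float(sys.box.min()) + 1e-9:
            raise InteractionError(
                f"real-space cutoff {r_cut} A exceeds half the box {sys.box.min()/2:g} A"
            )
        params = EwaldParams.from_accuracy(accuracy, r_cut, alpha=alpha)
        e_r, F_r, W_r = _coulomb_real(sys, nb, r_cut, alpha=params.alpha)
        e_k, F_k, W_k = _coulomb_recip(sys, params)
        e_s, F_s, W_s = _coulomb_self_intra(sys, params.alpha)
        report.energy_coul_real = e_r
        report.energy_coul_recip = e_k
        report.energy_coul_self = e_s
        report.virial += W_r + W_k + W_s
        site_F = F_r + F_k + F_s
    else:
        raise InteractionError(f"unknown coulomb method {coulomb!r}")
    _accumulate(sys, report, site_F, lj["F"])
    return report


def cg_single_point(cfg: Configuration, r_cut: float = 10.0,
                    coulomb: str = "ewald", accuracy: float = 1e-4,
                    lj_shift: bool = False, alpha: float = None,
                    lj_tail: bool = False) -> ForceReport:
    """Single-point evaluation in the coarse-grained formalism.

    Bead-bead LJ plus virtual-charge electrostatics; torques are referenced
    to the bead center (the oxygen/LJ site), to which only off-center sites
    contribute.  Isolated (non-periodic) configurations use the bare Coulomb
    sum without cutoff.
    """
    return _single_point(_system_from_cfg(cfg), r_cut, coulomb, accuracy,
                         lj_shift, alpha, lj_tail)


def aa_single_point(aa: AAFrame, spec: WaterModelSpec = None, box=None,
                    r_cut: float = 10.0, coulomb: str = "ewald",
                    accuracy: float = 1e-4, lj_shift: bool = False,
                    alpha: float = None, lj_tail: bool = False) -> ForceReport:
    """Single-point intermolecular energy in the atomistic formalism.

    Site-site Coulomb over the atomic point charges (Ewald under
    periodicity) plus oxygen-oxygen LJ; intramolecular interactions are
    excluded.  Per-molecule torques are referenced to the molecular COM.
    """
    if spec is not None and spec is not aa.species:
        aa = AAFrame(aa.coords, spec, box=aa.box, periodic=aa.periodic)
    return _single_point(_system_from_aa(aa, box=box), r_cut, coulomb,
                         accuracy, lj_shift, alpha, lj_tail)


def ewald_eval(cfg: Configuration, accuracy: float = 1e-6,
               r_cut: float = 10.0, alpha: float = None) -> ForceReport:
    """Electrostatic-only Ewald evaluation of a periodic configuration."""
    sys = _system_from_cfg(cfg)
    sys.lj_eps[:] = 0.0
    return _single_point(sys, r_cut, "ewald", accuracy, False, alpha)
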