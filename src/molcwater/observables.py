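"""Validation observables computed from trajectories.

Every estimator returns an :class:`ObservableResult` holding the value, a
block-average (or fit) standard error and enough metadata to reproduce the
estimate from the same trajectory.  Structural observables (RDFs) operate on
reverse-mapped atomistic frames so coarse-grained runs can be compared
directly against atomistic references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import units
from .rigid import AAFrame
from .trajio import Trajectory

__all__ = [
    "ObservableResult",
    "density",
    "rdf",
    "self_diffusion",
    "viscosity_gk",
    "stokes_einstein",
    "surface_tension",
    "enthalpy_vaporization",
]


class ObservableError(ValueError):
    pass


@dataclass
class ObservableResult:
    name: str
    value: float
    uncertainty: float
    units: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.uncertainty < 0:
            raise ObservableError("uncertainty must be non-negative")

    def __repr__(self):
        return (f"{self.name} = {self.value:.6g} +- {self.uncertainty:.2g} "
                f"{self.units}")


def _block_stats(series: np.ndarray, n_blocks: int = 5):
    """Mean and block-average standard error of a (possibly correlated) series."""
    series = np.asarray(series, dtype=float)
    if len(series) == 0:
        raise ObservableError("empty series")
    if len(series) < n_blocks:
        return float(series.mean()), float(series.std(ddof=0))
    blocks = np.array_split(series, n_blocks)
    means = np.array([b.mean() for b in blocks])
    err = means.std(ddof=1) / math.sqrt(n_blocks) if n_blocks > 1 else 0.0
    return float(series.mean()), float(err)


def _autocorr_fft(a: np.ndarray) -> np.ndarray:
    """Unbiased autocorrelation along axis 0 for each trailing column."""
    n = len(a)
    f = np.fft.rfft(a, n=2 * n, axis=0)
    acf = np.fft.irfft(f * f.conj(), n=2 * n, axis=0)[:n].real
    counts = np.arange(n, 0, -1).reshape((n,) + (1,) * (a.ndim - 1))
    return acf / counts


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def density(traj: Trajectory, n_blocks: int = 5) -> ObservableResult:
    """Time-averaged mass density in g/cm^3."""
    if len(traj) == 0:
        raise ObservableError("empty trajectory")
    masses = np.array([sp.bead_mass for sp in traj.species])
    rho = []
    for f in traj.frames:
        total_mass = masses[f.species_index].sum()
        rho.append(total_mass / np.prod(f.box) * units.DENSITY_GCM3)
    value, err = _block_stats(np.array(rho), n_blocks)
    return ObservableResult("density", value, err, "g/cm^3",
                            {"n_frames": len(traj), "n_blocks": n_blocks})


# ---------------------------------------------------------------------------
# radial distribution functions
# ---------------------------------------------------------------------------

def _element_indices(spec, element: str) -> np.ndarray:
    return np.array([i for i, s in enumerate(spec.atom_sites)
                     if s.name[0] == element and (s.mass > 0 or element == "M")])


def rdf(frames, pair: str = "OO", dr: float = 0.05,
        r_max: float = None) -> np.ndarray:
    """Site-site pair correlation function from periodic atomistic frames.

    ``frames`` is a sequence of :class:`AAFrame` (or a single one) with
    boxes set.  Intramolecular pairs are excluded from the histogram; the
    normalization uses the full ideal-gas pair density, so g -> 1 at large
    r.  Returns a (n_bins, 2) array of (bin center r, g(r)).
    """
    if isinstance(frames, AAFrame):
        frames = [frames]
    if pair not in ("OO", "OH", "HH"):
        raise ObservableError(f"unknown pair {pair!r}")
    el_a, el_b = pair[0], pair[1]
    first = frames[0]
    if first.box is None:
        raise ObservableError("RDF requires periodic frames with a box")
    if r_max is None:
        r_max = 0.5 * float(min(f.box.min() for f in frames))
    n_bins = int(round(r_max / dr))
    hist = np.zeros(n_bins)
    norm = 0.0
    for f in frames:
        if r_max > 0.5 * f.box.min() + 1e-9:
            raise ObservableError(
                f"r_max {r_max:g} exceeds half the smallest box edge "
                f"{f.box.min()/2:g}")
        ia = _element_indices(f.species, el_a)
        ib = _element_indices(f.species, el_b)
        pa = f.coords[:, ia, :].reshape(-1, 3)
        pb = f.coords[:, ib, :].reshape(-1, 3)
        mol_a = np.repeat(np.arange(f.n_molecules), len(ia))
        mol_b = np.repeat(np.arange(f.n_molecules), len(ib))
        d = pa[:, None, :] - pb[None, :, :]
        d -= f.box * np.round(d / f.box)
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        inter = mol_a[:, None] != mol_b[None, :]
        r = r[inter]
        h, _ = np.histogram(r, bins=n_bins, range=(0.0, r_max))
        hist += h
        V = float(np.prod(f.box))
        norm += len(pa) * len(pb) / V  # ordered pairs (self-pairs excluded below)
        if el_a == el_b:
            norm -= len(pa) / V
    edges = np.linspace(0.0, r_max, n_bins + 1)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = hist / (shell * norm)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return np.column_stack([centers, g])


# ---------------------------------------------------------------------------
# self-diffusion from the mean-square displacement
# ---------------------------------------------------------------------------

def _msd_multi_origin(x: np.ndarray) -> np.ndarray:
    """FFT-based multiple-time-origin MSD, averaged over beads.

    ``x`` is (n_frames, n_beads, 3) unwrapped coordinates.
    """
    nf = x.shape[0]
    x = x - x[0]  # translation invariance; keeps FFT round-off small
    s2 = _autocorr_fft(x).sum(axis=-1)  # (nf, nb)
    d = (x ** 2).sum(axis=-1)  # (nf, nb)
    dpad = np.vstack([d, np.zeros((1, d.shape[1]))])
    q = 2.0 * d.sum(axis=0)
    s1 = np.empty_like(d)
    for m in range(nf):
        q = q - dpad[m - 1] - dpad[nf - m]
        s1[m] = q / (nf - m)
    return (s1 - 2.0 * s2).mean(axis=1)


def self_diffusion(traj: Trajectory, fit_window=(0.1, 0.5),
                   diffusive_gate=(0.9, 1.1)) -> ObservableResult:
    """Einstein self-diffusion coefficient, 1e-9 m^2/s.

    D = slope(MSD vs t)/6 fitted over ``fit_window`` (fractions of the
    trajectory span).  A log-log slope outside ``diffusive_gate`` marks the
    fit non-diffusive in the metadata.
    """
    if len(traj) < 4:
        raise ObservableError("trajectory too short for an MSD fit")
    x = traj.unwrapped_positions()
    # remove the system COM drift (a net momentum, e.g. inherited from a
    # stochastic thermostat, would otherwise add a ballistic t^2 term)
    masses = np.array([sp.bead_mass for sp in traj.species])
    w = masses[traj[0].species_index]
    x = x - (w[None, :, None] * x).sum(axis=1, keepdims=True) / w.sum()
    t = traj.times - traj.times[0]
    msd = _msd_multi_origin(x)
    lo = int(fit_window[0] * len(t))
    hi = int(fit_window[1] * len(t))
    if hi - lo < 3 or hi > len(t):
        raise ObservableError("fit window outside the trajectory span")
    fit = stats.linregress(t[lo:hi], msd[lo:hi])
    with np.errstate(divide="ignore"):
        mask = (msd[lo:hi] > 0) & (t[lo:hi] > 0)
        loglog = stats.linregress(np.log(t[lo:hi][mask]),
                                  np.log(msd[lo:hi][mask])) if mask.sum() > 2 \
            else None
    ll_slope = float(loglog.slope) if loglog else float("nan")
    diffusive = bool(diffusive_gate[0] <= ll_slope <= diffusive_gate[1])
    d_val = fit.slope / 6.0 * units.DIFF_TO_1E9_M2S
    d_err = fit.stderr / 6.0 * units.DIFF_TO_1E9_M2S if fit.stderr else 0.0
    return ObservableResult(
        "self_diffusion", float(d_val), float(abs(d_err)), "1e-9 m^2/s",
        {"fit_window": tuple(fit_window), "loglog_slope": ll_slope,
         "diffusive": diffusive, "n_frames": len(traj)})


# ---------------------------------------------------------------------------
# Green-Kubo shear viscosity
# ---------------------------------------------------------------------------

def viscosity_gk(pressure_series: np.ndarray, V: float, T: float, dt: float,
                 plateau_factor: float = 10.0,
                 n_blocks: int = 5) -> ObservableResult:
    """Green-Kubo shear viscosity in mPa*s.

    ``pressure_series`` is (n_t, 3) off-diagonal pressure components
    (P_xy, P_xz, P_yz) in atm, sampled every ``dt`` fs in a box of volume
    ``V`` A^3 at temperature ``T``.  mu = V/(kB T) * integral of the
    stress autocorrelation, averaged over the three components; the
    integration window ends at ``plateau_factor`` times the 1/e decay time
    of the normalized autocorrelation (recorded in the metadata, together
    with the full running integral).
    """
    p = np.atleast_2d(np.asarray(pressure_series, dtype=float))
    if p.ndim == 2 and p.shape[1] not in (1, 3):
        p = p.T
    if len(p) < 10:
        raise ObservableError("stress series too short for a Green-Kubo integral")
    p = p - p.mean(axis=0)
    acf = _autocorr_fft(p).mean(axis=1)  # atm^2, averaged over components
    if acf[0] <= 0:
        return ObservableResult("viscosity", 0.0, 0.0, "mPa*s",
                                {"plateau_time_fs": 0.0})
    norm = acf / acf[0]
    below = np.nonzero(norm < math.exp(-1.0))[0]
    tau_idx = int(below[0]) if len(below) else len(acf) // 2
    upper = min(int(round(plateau_factor * max(tau_idx, 1))), len(acf) - 1)
    t = np.arange(len(acf)) * dt
    running = np.concatenate([[0.0],
                              np.cumsum(0.5 * (acf[1:] + acf[:-1]) * dt)])
    to_si = (units.ATM_TO_PA ** 2) * 1e-15 * (V * 1e-30) / (units.KB_SI * T)
    mu = running[upper] * to_si * 1e3
    # block error: independent sub-series, same integration window
    block_vals = []
    for b in np.array_split(p, n_blocks):
        if len(b) <= upper:
            continue
        a = _autocorr_fft(b - b.mean(axis=0)).mean(axis=1)
        r = np.concatenate([[0.0], np.cumsum(0.5 * (a[1:] + a[:-1]) * dt)])
        block_vals.append(r[min(upper, len(r) - 1)] * to_si * 1e3)
    err = (np.std(block_vals, ddof=1) / math.sqrt(len(block_vals))
           if len(block_vals) > 1 else 0.0)
    return ObservableResult(
        "viscosity", float(mu), float(err), "mPa*s",
        {"plateau_time_fs": float(t[upper]), "tau_1e_fs": float(t[tau_idx]),
         "running_integral_mPas": (running * to_si * 1e3),
         "times_fs": t})


def stokes_einstein(mu: float, T: float, r: float) -> float:
    """D* = kB T / (6 pi mu r) with stick boundary conditions, 1e-9 m^2/s.

    ``mu`` in mPa*s, ``r`` in A (default convention: half the bead LJ
    sigma, recorded by callers).
    """
    if mu <= 0 or r <= 0 or T <= 0:
        raise ObservableError("Stokes-Einstein needs positive mu, T and r")
    d = units.KB_SI * T / (6.0 * math.pi * (mu * 1e-3) * (r * 1e-10))
    return d / 1e-9


# ---------------------------------------------------------------------------
# surface tension (Kirkwood-Buff)
# ---------------------------------------------------------------------------

def _has_vacuum_gap(traj: Trajectory, n_bins: int = None,
                    threshold: float = 0.05) -> bool:
    """True if the z density profile has two consecutive (near-)empty bins.

    Requiring consecutive empty bins keeps sparse-but-uniform systems from
    being mistaken for slabs.
    """
    f = traj.frames[-1]
    n = len(f.positions)
    if n_bins is None:
        n_bins = max(6, min(20, n // 8))
    z = f.positions[:, 2] % f.box[2]
    hist, _ = np.histogram(z, bins=n_bins, range=(0.0, f.box[2]))
    empty = hist <= threshold * hist.mean()
    return bool(np.any(empty[1:] & empty[:-1]))


def surface_tension(slab_traj: Trajectory, n_blocks: int = 5,
                    check_gap: bool = True) -> ObservableResult:
    """Kirkwood-Buff surface tension of a z-slab geometry, mJ/m^2.

    gamma = (L_z / 2) <P_zz - (P_xx + P_yy)/2>; the factor 2 accounts for
    the two interfaces.  Refuses trajectories without a vacuum gap along z.
    """
    if check_gap and not _has_vacuum_gap(slab_traj):
        raise ObservableError("no vacuum gap along z: not a slab geometry")
    vals = []
    for f in slab_traj.frames:
        if f.pressure is None:
            raise ObservableError("slab trajectory has no pressure tensors")
        p = f.pressure
        vals.append(0.5 * f.box[2] * (p[2, 2] - 0.5 * (p[0, 0] + p[1, 1]))
                    * units.ATM_A_TO_MJ_M2)
    vals = np.array(vals)  # positive when tangential pressure < normal
    value, err = _block_stats(vals, n_blocks)
    return ObservableResult("surface_tension", value, err, "mJ/m^2",
                            {"n_frames": len(vals), "n_blocks": n_blocks})


# ---------------------------------------------------------------------------
# enthalpy of vaporization
# ---------------------------------------------------------------------------

def enthalpy_vaporization(liq_traj: Trajectory, T: float,
                          n_blocks: int = 5) -> ObservableResult:
    """Delta H_vap = -<U_inter>/N + R T for rigid molecules, kcal/mol.

    The gas phase of a rigid-molecule model has zero intermolecular
    potential energy, so only the liquid trajectory is needed.
    """
    u = liq_traj.potential_energies()
    n = liq_traj.n_beads
    vals = -u / n + units.R_GAS * T
    value, err = _block_stats(vals, n_blocks)
    return ObservableResult("enthalpy_vaporization", value, err, "kcal/mol",
                            {"T_K": T, "n_molecules": n, "n_blocks": n_blocks})
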