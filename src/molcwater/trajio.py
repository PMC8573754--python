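"""Trajectory container and text formats.

The native trajectory is a documented LAMMPS-dump-style text dialect with
quaternion, velocity and angular-momentum columns, plus optional per-frame
energy and pressure-tensor records.  It is lossless (full ``repr`` float
precision), diffable and desk-scale appropriate.  Atomistic exports use
standard XYZ or PDB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .forcefield import WaterModelSpec
from .rigid import Configuration, reverse_map

__all__ = ["TrajectoryFrame", "Trajectory", "write_traj", "read_traj",
           "export_aa", "TrajectoryFormatError"]

_ATOM_COLS = ("id species x y z qw qx qy qz vx vy vz Lx Ly Lz ix iy iz")


class TrajectoryFormatError(ValueError):
    pass


@dataclass
class TrajectoryFrame:
    """One stored frame: wrapped positions + image flags + optional records."""

    step: int
    time: float  # fs
    box: np.ndarray  # (3,)
    positions: np.ndarray  # (N, 3) wrapped into [0, box)
    quats: np.ndarray  # (N, 4)
    vels: np.ndarray  # (N, 3)
    angmom: np.ndarray  # (N, 3)
    images: np.ndarray  # (N, 3) int
    species_index: np.ndarray = None  # (N,)
    energies: dict = None  # keys: total, lj, coul_real, coul_recip, coul_self, kinetic
    pressure: np.ndarray = None  # (3, 3) atm

    def __post_init__(self):
        n = len(self.positions)
        if self.species_index is None:
            self.species_index = np.zeros(n, dtype=int)

    @property
    def unwrapped(self) -> np.ndarray:
        return self.positions + self.images * self.box


@dataclass
class Trajectory:
    """Time-ordered frames sharing one species list."""

    species: list
    frames: list = field(default_factory=list)

    def append(self, frame: TrajectoryFrame) -> None:
        if self.frames and len(frame.positions) != len(self.frames[0].positions):
            raise TrajectoryFormatError("bead count changed between frames")
        self.frames.append(frame)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> TrajectoryFrame:
        return self.frames[i]

    @property
    def n_beads(self) -> int:
        return len(self.frames[0].positions)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def boxes(self) -> np.ndarray:
        return np.array([f.box for f in self.frames])

    def unwrapped_positions(self) -> np.ndarray:
        """(n_frames, N, 3) coordinates continued across the boundaries."""
        return np.array([f.unwrapped for f in self.frames])

    def pressures(self) -> np.ndarray:
        if any(f.pressure is None for f in self.frames):
            raise TrajectoryFormatError("trajectory has no stored pressure tensors")
        return np.array([f.pressure for f in self.frames])

    def potential_energies(self) -> np.ndarray:
        if any(f.energies is None for f in self.frames):
            raise TrajectoryFormatError("trajectory has no stored energies")
        return np.array([f.energies["total"] for f in self.frames])

    def configuration(self, i: int = -1, periodic: bool = True) -> Configuration:
        f = self.frames[i]
        return Configuration(P=f.unwrapped, q=f.quats.copy(), box=f.box.copy(),
                             species=list(self.species),
                             species_index=f.species_index.copy(),
                             v=f.vels.copy(), L=f.angmom.copy(), periodic=periodic)


# ---------------------------------------------------------------------------
# native text format
# ---------------------------------------------------------------------------

def write_traj(path, traj: Trajectory) -> None:
    with open(path, "w") as fh:
        for f in traj.frames:
            norms = np.linalg.norm(f.quats, axis=-1)
            quats = f.quats
            if np.abs(norms - 1.0).max() > 1e-12:
                quats = quats / norms[:, None]
            fh.write("ITEM: TIMESTEP\n%d\n" % f.step)
            fh.write("ITEM: TIME\n%r\n" % float(f.time))
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % len(f.positions))
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for d in range(3):
                fh.write("%r %r\n" % (0.0, float(f.box[d])))
            if f.energies is not None:
                keys = sorted(f.energies)
                fh.write("ITEM: ENERGIES %s\n" % " ".join(keys))
                fh.write(" ".join(repr(float(f.energies[k])) for k in keys) + "\n")
            if f.pressure is not None:
                fh.write("ITEM: PRESSURE xx yy zz xy xz yz\n")
                p = f.pressure
                fh.write(" ".join(repr(float(x)) for x in
                                  (p[0, 0], p[1, 1], p[2, 2],
                                   p[0, 1], p[0, 2], p[1, 2])) + "\n")
            fh.write("ITEM: ATOMS %s\n" % _ATOM_COLS)
            for i in range(len(f.positions)):
                floats = (*f.positions[i], *quats[i], *f.vels[i],
                          *f.angmom[i])
                fh.write("%d %d %s %s\n" % (
                    i + 1, int(f.species_index[i]),
                    " ".join(repr(float(x)) for x in floats),
                    " ".join(str(int(x)) for x in f.images[i])))


def _expect(lines, lineno, startswith):
    if lineno >= len(lines):
        raise TrajectoryFormatError(f"truncated file: expected {startswith!r} "
                                    f"after line {lineno}")
    if not lines[lineno].startswith(startswith):
        raise TrajectoryFormatError(
            f"line {lineno + 1}: expected {startswith!r}, got "
            f"{lines[lineno][:40]!r}")
    return lineno + 1


def read_traj(path, species: list = None) -> Trajectory:
    """Parse the native dialect; renormalizes slightly non-unit quaternions
    (warning) and rejects deviations beyond 1e-6."""
    lines = Path(path).read_text().splitlines()
    traj = Trajectory(species=species or [])
    i = 0
    n_prev = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        i = _expect(lines, i - 1 + 1, "ITEM: TIMESTEP")
        step = int(lines[i]); i += 1
        i = _expect(lines, i, "ITEM: TIME")
        time = float(lines[i]); i += 1
        i = _expect(lines, i, "ITEM: NUMBER OF ATOMS")
        n = int(lines[i]); i += 1
        if n_prev is not None and n != n_prev:
            raise TrajectoryFormatError(f"line {i}: bead count changed "
                                        f"({n_prev} -> {n})")
        n_prev = n
        i = _expect(lines, i, "ITEM: BOX BOUNDS")
        box = np.empty(3)
        for d in range(3):
            lo, hi = map(float, lines[i].split()); i += 1
            box[d] = hi - lo
        energies = None
        pressure = None
        while i < len(lines) and not lines[i].startswith("ITEM: ATOMS"):
            if lines[i].startswith("ITEM: ENERGIES"):
                keys = lines[i].split()[2:]; i += 1
                vals = list(map(float, lines[i].split())); i += 1
                energies = dict(zip(keys, vals))
            elif lines[i].startswith("ITEM: PRESSURE"):
                i += 1
                xx, yy, zz, xy, xz, yz = map(float, lines[i].split()); i += 1
                pressure = np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])
            else:
                raise TrajectoryFormatError(
                    f"line {i + 1}: unrecognized record {lines[i][:40]!r}")
        i = _expect(lines, i, "ITEM: ATOMS")
        pos = np.empty((n, 3)); quats = np.empty((n, 4))
        vels = np.empty((n, 3)); angmom = np.empty((n, 3))
        images = np.empty((n, 3), dtype=int)
        spidx = np.empty(n, dtype=int)
        for a in range(n):
            if i >= len(lines) or not lines[i].strip():
                raise TrajectoryFormatError(
                    f"truncated file: frame at step {step} ends at line {i}")
            parts = lines[i].split(); i += 1
            if len(parts) != 18:
                raise TrajectoryFormatError(
                    f"line {i}: expected 18 columns, got {len(parts)}")
            spidx[a] = int(parts[1])
            vals = list(map(float, parts[2:]))
            pos[a] = vals[0:3]; quats[a] = vals[3:7]
            vels[a] = vals[7:10]; angmom[a] = vals[10:13]
            images[a] = [int(x) for x in parts[15:18]]
        norms = np.linalg.norm(quats, axis=-1)
        dev = np.abs(norms - 1.0).max()
        if dev > 1e-6:
            raise TrajectoryFormatError(
                f"frame at step {step}: quaternion norm off by {dev:.2e}")
        if dev > 1e-12:
            warnings.warn(f"renormalizing quaternions (max deviation {dev:.2e})")
            quats /= norms[:, None]
        traj.append(TrajectoryFrame(step=step, time=time, box=box,
                                    positions=pos, quats=quats, vels=vels,
                                    angmom=angmom, images=images,
                                    species_index=spidx, energies=energies,
                                    pressure=pressure))
    return traj


# ---------------------------------------------------------------------------
# atomistic export
# ---------------------------------------------------------------------------

def export_aa(path, frames, spec: WaterModelSpec = None, fmt: str = None,
              include_massless: bool = False) -> None:
    """Write reverse-mapped atomistic coordinates as XYZ or PDB.

    ``frames`` may be a Trajectory, a Configuration or a list of
    Configurations.  Massless virtual sites (the TIP4P M site) are omitted
    from XYZ output unless ``include_massless`` is set; PDB always includes
    every site (one residue per molecule, HETATM records).
    """
    path = Path(path)
    fmt = fmt or ("pdb" if path.suffix.lower() == ".pdb" else "xyz")
    if isinstance(frames, Trajectory):
        cfgs = [frames.configuration(i) for i in range(len(frames))]
    elif isinstance(frames, Configuration):
        cfgs = [frames]
    else:
        cfgs = list(frames)
    with open(path, "w") as fh:
        for cfg in cfgs:
            aa = reverse_map(cfg)
            sp = aa.species
            keep = [k for k, s in enumerate(sp.atom_sites)
                    if include_massless or s.mass > 0 or fmt == "pdb"]
            if fmt == "xyz":
                fh.write("%d\n" % (aa.n_molecules * len(keep)))
                fh.write("reverse-mapped %s frame\n" % sp.name)
                for mol in aa.coords:
                    for k in keep:
                        el = sp.atom_sites[k].name[0]
                        fh.write("%s %.10f %.10f %.10f\n" % (el, *mol[k]))
            elif fmt == "pdb":
                serial = 0
                for imol, mol in enumerate(aa.coords):
                    for k in keep:
                        serial += 1
                        name = sp.atom_sites[k].name
                        fh.write(
                            "HETATM%5d %-4s HOH  %4d    %8.3f%8.3f%8.3f"
                            "  1.00  0.00          %2s\n"
                            % (serial, name, imol + 1, *mol[k], name[0]))
                fh.write("END\n")
            else:
                raise TrajectoryFormatError(f"unknown export format {fmt!r}")
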