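# molcwater

Coarse-grained molecular dynamics of liquid water with **one rigid sphere
per molecule and off-center virtual charges** — a re-expression of the
classic rigid three/four-site water models (SPC/E, TIP3P-Ew, TIP4P/2005)
that keeps their electrostatics exactly while unlocking a 10 fs
integration timestep.

## Who this is for

Researchers building mesoscopic / coarse-grained simulations (biomolecular
solvation, interfacial and wetting problems, nanofluidics) who need water
that is cheap to integrate but keeps near-atomistic structure, dynamics and
electrostatics, and researchers studying the coarse-graining methodology
itself.

## The model

Each rigid water molecule is replaced by a single spherical bead:

- **mass** = the molecular mass m = 18.0154 g/mol,
- **radius** = the Lennard-Jones sigma of the parent model,
- **short range**: one 12-6 Lennard-Jones interaction between bead centers
  (the sphere–sphere limit of the generalized Gay–Berne potential),
- **electrostatics**: the *unchanged* point charges of the atomistic model,
  carried rigidly inside the bead at body-frame offsets S_i and
  reconstructed each step from the bead position P and unit quaternion q:

      R_i = P + R(q) S_i .

The Coulomb pair energy is U = C q1 q2 / |R1 − R2| with
C = 332.06371 kcal·Å/(mol·e²).  Because R_i depends on P only through a
translation, the force on the parent bead equals the force on the charge,
F2 = −F1, and each charge contributes the torque (R_i − P) × F_i about the
bead center.  Long-range electrostatics use a classic Ewald summation over
the virtual sites (erfc-damped real space, reciprocal sum, self term, and
rigid intra-bead exclusions).

An arbitrary rigid atomistic configuration mapped onto beads therefore has
**exactly the same intermolecular energy in both representations** — the
coarse model is a change of coordinates, not an approximation.  What does
change is the inertia: the solid-sphere moment of inertia
(2/5) m sigma² is far larger than the molecular one, which suppresses fast
librations and lets the rigid-body integrator (velocity Verlet +
self-consistent midpoint "Richardson" quaternion update) take 10 fs steps.

The package covers the full validation loop: AA↔CG mapping and reverse
mapping (backmapping), NVE/NVT/NPT dynamics, and the observables used to
judge water models — density, radial distribution functions on
reverse-mapped frames, self-diffusion from the mean-square displacement,
Green–Kubo shear viscosity, the Stokes–Einstein cross-check
D* = k_B T/(6 pi mu r), Kirkwood–Buff surface tension of slabs, and the
enthalpy of vaporization ΔH_vap = −⟨U⟩/N + RT.

## A worked example

```bash
python examples/energy_equivalence.py
```

```
CG formalism:  -42.947973545935 kcal/mol
AA formalism:  -42.947973545935 kcal/mol
difference:    +0.000e+00 kcal/mol
```

The two numbers are the single-point intermolecular energy of the same
27-molecule SPC/E configuration computed (i) from beads + off-center
charges and (ii) from atomistic site–site sums on the reverse-mapped
coordinates; their agreement to machine precision is the model's defining
property.  A short isothermal–isobaric run shows the physics that follows
from it:

```bash
python examples/npt_density.py
```

```
density: 1.002 +- 0.004 g/cm^3 (30 ps, 64 molecules, 10 fs timestep)
enthalpy of vaporization: 11.74 +- 0.04 kcal/mol
```

i.e. liquid water at 298 K / 1 atm simulated with a 10 fs timestep lands
within a percent of the experimental density (0.997 g/cm³), with the
cohesive energy of the parent SPC/E model.  The other scripts in
`examples/` each demonstrate one capability (Ewald vs the Madelung
constant, NVE conservation, backmapped RDFs, transport estimators).

There is also a thin CLI (`molcwater run|map|unmap|energy|rdf|msd|visc|
gamma|density|hvap|make-fixture`) over the same library functions; see
`molcwater --help`.

## Layout

```
src/molcwater/
  forcefield.py   # water-model parameter sets and their CG re-expression
  rigid.py        # quaternions, bead states, AA<->CG (reverse) mapping
  interactions.py # LJ + off-center-charge Coulomb + Ewald, forces/torques
  dynamics.py     # rigid-body integrator, thermostats, barostat
  observables.py  # density, RDF, MSD, Green-Kubo, surface tension, Hvap
  trajio.py       # text trajectory dialect, XYZ/PDB export
  fixtures.py     # deterministic synthetic systems for testing
  cli.py          # thin command-line layer
  data/*.yaml     # SPC/E, TIP3P-Ew, TIP4P/2005 parameter files
docs/methods.md   # model, algorithms, numerical choices, limitations
examples/         # one narrative script per capability
```
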