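# Methods

This note records the model, the algorithms and the numerical choices the
package makes, including the ones that were genuinely open.

## Model

A rigid n-site water molecule (SPC/E, TIP3P-Ew or TIP4P/2005; parameters
shipped verbatim from the original parameterizations in
`src/molcwater/data/`) is re-expressed as one spherical bead.  The bead
origin sits on the oxygen — which is also the single Lennard-Jones site of
all three models — and the bead radius equals the LJ sigma.  The body
frame is fixed by convention: molecular C2 axis along +x (towards the
hydrogens), molecule in the z = 0 plane, hydrogens symmetric about x.  Any
frame with the hydrogens at z = 0 is equivalent up to a fixed rotation;
this one makes the TIP4P M site sit at (0.1546, 0, 0) Å.

The point charges of the atomistic model are copied 1-to-1 into the bead
as body-frame offsets ("off-center charges") and reconstructed at run time
as R_i = P + R(q) S_i from the bead position P and the scalar-first,
body-to-lab unit quaternion q.  They are never integrated independently.
Consequently the intermolecular energy of a mapped configuration is
identical in the atomistic and coarse-grained formalisms; the test suite
asserts this to 1e-10 relative over random configurations of all three
models, and the two code paths are genuinely distinct (atomistic site-site
sums on coordinates vs bead reconstruction).

Units: Å, kcal/mol, g/mol, fs, elementary charge;
C = 332.06371 kcal·Å/(mol·e²), k_B = 0.0019872041 kcal/(mol·K).

## Interactions

- **Lennard-Jones** 12-6 between bead centers, truncated at `r_cut`
  (default 10 Å, configurable).  Unshifted by default; `lj_shift=True`
  removes the energy discontinuity at the cutoff (used for NVE
  conservation runs), `lj_tail=True` adds the standard homogeneous-fluid
  long-range corrections to energy and pressure (used for NPT runs — the
  tail pressure is ≈ −900 atm at r_cut = 6–7 Å and without it the barostat
  equilibrates several percent under-dense; kept off for slabs, where the
  homogeneity assumption fails).
- **Electrostatics**: classic Ewald over all virtual sites.  Real space:
  erfc-damped site-site sum over inter-bead pairs under the minimum-image
  convention (site pairs are pruned by a bead-level neighbor list, which
  cannot change the result because a site pair can only be in range if its
  parent beads are within `r_cut + 2·max|S|`).  Reciprocal space: direct
  k-sum with per-axis complex-exponential tables (a numba kernel when the
  problem is large enough).  Rigid intra-bead exclusions are handled by
  subtracting the erf-screened intra-bead term from the reciprocal sum;
  those correction forces are central with zero lever arm, so they cancel
  in the bead force and torque and only enter the virial.
- **Accuracy parameter**: `alpha = (sqrt(-ln acc) + 1)/r_cut`,
  `k_cut = 2 alpha (sqrt(-ln acc) + 1)`.  The +1 margin (beyond the usual
  single-pair heuristic) makes the total energy independent of the
  splitting parameter to within `acc` over a factor-of-two range in alpha,
  which is how the solver is validated.  Isolated (non-periodic)
  configurations use the bare Coulomb sum without cutoff.
- **Forces and torques**: site forces are summed onto the parent bead;
  torques are lever-arm cross products about the bead center (CG
  formalism) or the molecular COM (atomistic formalism) — the energy is
  reference-independent, only the torque bookkeeping differs.  All forces
  and torques are validated against central finite differences of the
  energy under translations and body rotations (relative error < 1e-6).
- **Virial / pressure**: molecular (bead-centered) virial tensor,
  W_mol = W_atomic − Σ_sites F_site ⊗ (r_site − P_parent), with the
  standard reciprocal-space stress tensor.  Validated against a
  finite-difference volume derivative of the energy.

## Mapping

`map_to_cg` places the bead on the oxygen site and extracts the quaternion
by an orthogonal Procrustes fit (scipy `Rotation.align_vectors`) of the
body-frame site template to the observed sites — exact for exactly rigid
molecules, and the natural choice since nothing pins down the extraction
otherwise.  Inputs that deviate from the rigid template by more than a
tolerance (default 1e-3 Å) are rejected.  `reverse_map` rebuilds all atom
sites from (P, q); round trips are exact to better than 1e-8 Å.

## Dynamics

Velocity Verlet for translation; angular momentum half-kicked by the
torque; the quaternion advanced at constant L by iterating the midpoint
quaternion derivative to self-consistency (tolerance 1e-12, then
renormalized) — the Richardson-style scheme that permits long timesteps.
The update handles a full (non-diagonal) body inertia tensor.

Two inertia modes:

- `sphere` (the coarse-grained mode): isotropic solid-sphere tensor
  (2/5) m r² with r = sigma by default (`sphere_radius_factor`
  configurable — the sphere density convention is not uniquely determined
  by physics, so the factor is exposed rather than asserted).  Rotation is
  referenced to the bead center.
- `atomistic` (the control mode): point-mass inertia about the molecular
  COM; the integrator propagates the COM (torque and inertia about it) and
  recovers the bead origin from the quaternion.  This mimics a rigid
  atomistic integrator and needs the usual 1–2 fs timestep.

The sphere inertia is ~30× the mean atomistic one for these radii; it is
this suppression of fast librations that makes 10 fs stable (verified:
125 beads, 100 ps NVT at 10 fs, no blow-up, density and temperature
matching a 1 fs control).  Integrator order is verified by the ~4×
reduction of the energy-error amplitude under timestep halving.  "Drift"
is always quoted as the secular trend (difference of first/last 1-ps block
means); the instantaneous oscillation is bounded and O(dt²).

Thermostats: Langevin (default; robust, exact target temperature via the
exponential memory kernel) and a single Nosé–Hoover chain (used for
transport runs, since stochastic thermostats bias Green–Kubo integrals and
suppress diffusion).  Barostat: isotropic Berendsen with compressibility
4.5e-5 atm⁻¹ — an approximate ensemble, adequate for densities; the box
scaling per step is clamped to ±1%.  Velocity initialization samples
Maxwell–Boltzmann velocities and principal-frame angular momenta, removes
net linear momentum, and rescales both reservoirs so the instantaneous
kinetic temperature matches the target exactly.  Blow-up detection halts
on any non-finite coordinate or |force| > 1e6 kcal/mol/Å with the
offending configuration attached.  All stochastic elements are driven by a
single seeded generator; equal seeds give bit-identical trajectories.

## Observables

- **Density**: N m / V per frame, block-averaged (5 blocks throughout).
- **RDF**: computed on reverse-mapped atomistic frames; intramolecular
  pairs excluded from the histogram while the normalization keeps the full
  ideal-gas pair density, so g → 1 at large r.
- **Self-diffusion**: FFT-based multiple-origin MSD computed in the system
  COM frame (a residual net momentum, e.g. inherited from a stochastic
  thermostat, would otherwise contribute a ballistic t² term); Einstein
  relation
  D = slope/6 over a fit window of [10%, 50%] of the span, with a log-log
  slope gate (1.0 ± 0.1) recorded as a diffusive/non-diffusive flag.
- **Viscosity**: Green–Kubo integral of the off-diagonal pressure-tensor
  autocorrelation, averaged over the three components; the integration
  window ends at 10× the 1/e decay time of the normalized ACF (recorded,
  with the full running integral, in the metadata).  The estimator is
  validated against the closed form mu = V A² tau_c / (k_B T) for an
  Ornstein–Uhlenbeck stress series.
- **Stokes–Einstein**: D* = k_B T/(6 pi mu r), stick boundary; the radius
  convention is ambiguous in principle, so r defaults to sigma/2 and is
  recorded with the output.
- **Surface tension**: Kirkwood–Buff, gamma = (L_z/2)⟨P_zz −
  (P_xx+P_yy)/2⟩ (two interfaces), after a vacuum-gap check on the z
  density profile (two consecutive near-empty bins, so sparse-but-uniform
  systems are not mistaken for slabs).
- **Enthalpy of vaporization**: ΔH_vap = −⟨U_inter⟩/N + RT (rigid
  molecules: the gas-phase intermolecular energy is zero).

## Synthetic systems and what passing tests show

The fixtures generate cubic water lattices at a target density with
uniformly random orientations (Shoemake sampling), dimer scans, rock-salt
ion lattices (Madelung check against an Evjen direct summation), ideal-gas
frames, slabs with a vacuum gap, Ornstein–Uhlenbeck stress series and
Gaussian random walks — all bit-reproducible from (parameters, seed).
They emulate the *conditions* of bulk- and slab-water studies at desk
scale; they are not pre-equilibrated liquid structures, and the synthetic
series have by construction none of the slow collective modes of a real
liquid.  Passing estimator tests therefore demonstrates correctness of the
estimators, not the convergence of any particular short simulation.

## Problem sizes

The shipped runs use 2–125 molecules and 2–100 ps: large enough for the
exact identities (energy equivalence, mapping, gradients) to be fully
meaningful — they hold configuration by configuration — and for densities
and ΔH_vap to land within a few percent, while transport coefficients
(D, mu, gamma) from such runs carry tens-of-percent statistical error and
are reported with block-average uncertainties.

## Known limitations

- Orthorhombic periodic boxes only; rigid molecules only; one LJ site per
  molecule; spheres (no ellipsoidal shape anisotropy).
- Classic Ewald (no mesh/PPPM), O(N^1.5)-ish; fine at desk scale.
- Berendsen NPT is not a true isothermal–isobaric ensemble.
- The slab electrostatics use plain 3D periodicity (a large vacuum gap,
  no 2D slab correction term).
- The inertia-mode torque reference differs between CG (bead center) and
  atomistic (COM) dynamics; with the COM only ~0.065 Å from the oxygen the
  induced differences are small but real, and they are the main source of
  the slightly softer structure of the CG liquid.
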