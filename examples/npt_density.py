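"""Liquid-water density from a short NPT run with a 10 fs timestep.

The coarse-grained spheres tolerate a 10 fs timestep because their
solid-sphere inertia is far larger than the atomistic one, suppressing the
fast librations.  This runs a small 64-molecule SPC/E box at 298 K / 1 atm
(Berendsen barostat) and prints the time-averaged density; at this size and
length the value carries a few-percent statistical/finite-size error.
"""

from molcwater import RunConfig, density, enthalpy_vaporization, \
    initialize_velocities, run
from molcwater.fixtures import cubic_lattice_water

cfg = cubic_lattice_water("SPC-E", 64, 0.997, seed=11)
cfg = initialize_velocities(cfg, 298.0, 11)
base = dict(T_target=298.0, r_cut=6.0, ewald_accuracy=1e-4, lj_tail=True)
eq = run(cfg, RunConfig(timestep=10.0, n_steps=1000, ensemble="NPT",
                        tdamp=500.0, pdamp=2000.0, seed=11,
                        output_every=200, **base))
prod = run(eq.configuration(-1),
           RunConfig(timestep=10.0, n_steps=2000, ensemble="NPT",
                     tdamp=500.0, pdamp=2000.0, seed=12, output_every=10,
                     **base))
rho = density(prod)
hv = enthalpy_vaporization(prod, 298.0)
print(f"density: {rho.value:.3f} +- {rho.uncertainty:.3f} g/cm^3 "
      f"(30 ps, 64 molecules, 10 fs timestep)")
print(f"enthalpy of vaporization: {hv.value:.2f} +- {hv.uncertainty:.2f} "
      f"kcal/mol")
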