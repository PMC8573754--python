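"""Unit system and physical constants.

The package works in the "real"-style MD unit system: lengths in Angstrom,
energies in kcal/mol, masses in g/mol, times in fs, charges in units of the
elementary charge e.  Velocities are A/fs and angular momenta g/mol*A^2/fs.
Conversion factors below bridge the mechanical units (mass*length^2/time^2)
and the energy unit, and translate derived observables to the units they
are conventionally reported in (g/cm^3, atm, mPa*s, mJ/m^2, 1e-9 m^2/s).
"""

from __future__ import annotations

import math

#: Coulomb constant, kcal*A/(mol*e^2): U = COULOMB * q1*q2 / r.
COULOMB = 332.06371

#: Boltzmann constant, kcal/(mol*K).
KB = 0.0019872041

#: Molar gas constant in the energy unit, kcal/(mol*K) (same number as KB).
R_GAS = KB

#: kcal/mol per (g/mol * A^2 / fs^2): 1 g/mol*A^2/fs^2 = 1e7 J/mol.
MVV2E = 1.0e7 / 4184.0

#: Inverse of MVV2E: acceleration = force[kcal/mol/A] * E2MVV / mass[g/mol].
E2MVV = 1.0 / MVV2E

#: Boltzmann constant in mechanical units, g/mol*A^2/(fs^2*K).
KB_MECH = KB * E2MVV

#: kcal/mol/A^3 -> atm.
P2ATM = 68568.415

#: g/mol/A^3 -> g/cm^3 (1/N_A * 1e24).
DENSITY_GCM3 = 1.66053906892

#: A^2/fs -> 1e-9 m^2/s (for diffusion coefficients, slope/6 already taken).
DIFF_TO_1E9_M2S = 1.0e4

#: atm*A -> mJ/m^2 (for surface tension).
ATM_A_TO_MJ_M2 = 101325.0 * 1.0e-10 * 1.0e3

#: Boltzmann constant, J/K (SI, for Stokes-Einstein and Green-Kubo).
KB_SI = 1.380649e-23

#: atm -> Pa.
ATM_TO_PA = 101325.0

SQRT_PI = math.sqrt(math.pi)
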