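"""Transport-coefficient estimators checked on analytic synthetic inputs.

Each estimator is exercised on data with a known answer: a Gaussian random
walk (D = s^2/2dt), an exponentially correlated stress series
(mu = V A^2 tau_c / kB T), and the Stokes-Einstein relation tying the two
together.  Printed ratios near 1 mean the estimators are unbiased.
"""

import numpy as np

from molcwater import self_diffusion, stokes_einstein, units, viscosity_gk
from molcwater.fixtures import random_walk_traj, synthetic_stress_series

# self-diffusion from a random walk
s, dt = 0.05, 10.0
traj = random_walk_traj("SPC-E", n_beads=400, step_std=s, dt=dt,
                        n_frames=400, seed=1)
d = self_diffusion(traj)
d_exact = s ** 2 / (2 * dt) * units.DIFF_TO_1E9_M2S
print(f"random-walk D: {d.value:.3f} (exact {d_exact:.3f}) "
      f"[1e-9 m^2/s], ratio {d.value / d_exact:.3f}")

# Green-Kubo viscosity from an Ornstein-Uhlenbeck stress series
A, tau, V, T = 60.0, 150.0, 5000.0, 298.0
series = synthetic_stress_series(A, tau, dt, 100000, seed=2)
mu = viscosity_gk(series, V, T, dt)
mu_exact = (V * 1e-30) * (A * units.ATM_TO_PA) ** 2 * (tau * 1e-15) \
    / (units.KB_SI * T) * 1e3
print(f"Green-Kubo mu: {mu.value:.4f} (exact {mu_exact:.4f}) [mPa*s], "
      f"ratio {mu.value / mu_exact:.3f}")

# Stokes-Einstein: D* from mu at the bead hydrodynamic radius
d_star = stokes_einstein(1.0, 298.0, 1.583)  # mu = 1 mPa*s, r = sigma/2
print(f"Stokes-Einstein D*(mu=1 mPa*s, r=1.583 A) = {d_star:.2f} "
      f"[1e-9 m^2/s]")
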