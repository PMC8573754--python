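"""Ewald electrostatics validated on rock salt.

Builds a periodic lattice of +-1 e point beads with nearest-neighbor
distance a and recovers the Madelung constant from the Ewald energy per ion
pair, E = -M C / a with M = 1.747565.  The printed relative error is the
accuracy of the long-range solver.
"""

from molcwater import ewald_eval, units
from molcwater.fixtures import rocksalt

a = 2.82  # A, NaCl nearest-neighbor distance
cfg = rocksalt(a=a, n_cells=2)
rep = ewald_eval(cfg, accuracy=1e-7, r_cut=5.0)
per_pair = rep.energy_coul / (cfg.n_beads / 2)
m_computed = -per_pair * a / units.COULOMB

print(f"{cfg.n_beads} ions, a = {a} A")
print(f"Ewald energy per ion pair: {per_pair:.6f} kcal/mol")
print(f"Madelung constant: {m_computed:.7f} (reference 1.7475646)")
print(f"relative error: {abs(m_computed - 1.7475646) / 1.7475646:.2e}")
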