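# SPC/E rigid three-site water model (extended simple point charge).
# Units: A, e, kcal/mol, g/mol.
schema: molcwater-params-1
name: SPC-E
geometry:
  oh_length: 1.0
  hoh_angle_deg: 109.47
charges:
  O: -0.8476
  H: 0.4238
lj:
  sigma: 3.166
  epsilon: 0.15535   # 0.650 kJ/mol
masses:
  O: 15.9994
  H: 1.008
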