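# TIP3P-Ew: three-site TIP3P reparameterized for Ewald electrostatics.
# Units: A, e, kcal/mol, g/mol.
schema: molcwater-params-1
name: Tip3P-Ew
geometry:
  oh_length: 0.9572
  hoh_angle_deg: 104.52
charges:
  O: -0.830
  H: 0.415
lj:
  sigma: 3.188
  epsilon: 0.102
masses:
  O: 15.9994
  H: 1.008
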