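# TIP4P/2005: four-site rigid water; the negative charge sits on a massless
# M site displaced 0.1546 A from the oxygen along the HOH bisector.
# Units: A, e, kcal/mol, g/mol.
schema: molcwater-params-1
name: Tip4P-05
geometry:
  oh_length: 0.9572
  hoh_angle_deg: 104.52
charges:
  O: 0.0
  H: 0.5564
lj:
  sigma: 3.1589
  epsilon: 0.18521   # 0.7749 kJ/mol
masses:
  O: 15.9994
  H: 1.008
msite:
  distance: 0.1546
  charge: -1.1128
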