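# Additive atomic polarizability contributions (A^3) for the POL descriptor:
# average molecular polarizability as the sum of per-atom terms, after the
# additive atomic-hybrid schemes of Miller (element-averaged values).
# POL(molecule) = sum over atoms of contribution[element].
contributions:
  H: 0.387
  C: 1.061
  N: 0.964
  O: 0.637
  F: 0.296
  P: 1.538
  S: 3.000
  Cl: 2.315
  Br: 3.013
  I: 5.415
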