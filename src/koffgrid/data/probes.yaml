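# Probe and atom parameters for the molecular-interaction-field energy function.
#
# Energy model (per probe--atom pair, r in Angstrom, energies in kcal/mol):
#   E(r) = 4*eps_ij*((sig_ij/r)^12 - (sig_ij/r)^6)          Lennard-Jones 12-6
#        + 332.06 * q_atom * q_probe / (4*r * r)            Coulomb, eps(r) = 4r
#        + s_hb * (2*(r0/r)^6 - 3*(r0/r)^4)                 6-4 H-bond well,
#                                                           depth s_hb at r = r0,
#                                                           donor/acceptor pairs only
# Lorentz-Berthelot mixing: sig_ij = (sig_a + sig_p)/2, eps_ij = sqrt(eps_a*eps_p).
# Atoms farther than the cutoff contribute zero; r is clamped below at 0.1 A.
#
# The nine probes model the functional groups classically used for grid-based
# interaction fields: water, a dispersion-only hydrophobic probe, carbonyl and
# carboxy oxygens, amide NH, sp2 aza nitrogen, cationic NH3+ and anionic
# phenolate O-.  BOTH is not evaluated directly: its field is the pointwise
# minimum of the OH2 and DRY fields (amphipathic probe).
#
# These parameters are this package's own documented defaults (LJ values
# derived from the UFF set, H-bond depths chosen so charged probes bind more
# strongly than neutrals); edit and pass via --probe-table to override.

probes:
  OH2:   {charge:  0.00, lj_epsilon: 0.152, lj_sigma: 3.15, hbond_role: both,     hbond_strength: 4.0, hbond_r0: 2.9}
  DRY:   {charge:  0.00, lj_epsilon: 0.210, lj_sigma: 3.40, hbond_role: none,     hbond_strength: 0.0, hbond_r0: 2.9}
  O:     {charge: -0.30, lj_epsilon: 0.060, lj_sigma: 3.12, hbond_role: acceptor, hbond_strength: 3.0, hbond_r0: 2.9}
  "O::": {charge: -0.45, lj_epsilon: 0.060, lj_sigma: 3.12, hbond_role: acceptor, hbond_strength: 3.5, hbond_r0: 2.9}
  N1:    {charge:  0.25, lj_epsilon: 0.069, lj_sigma: 3.26, hbond_role: donor,    hbond_strength: 2.5, hbond_r0: 2.9}
  "N:=": {charge: -0.20, lj_epsilon: 0.069, lj_sigma: 3.26, hbond_role: acceptor, hbond_strength: 2.8, hbond_r0: 2.9}
  "N3+": {charge:  1.00, lj_epsilon: 0.069, lj_sigma: 3.26, hbond_role: donor,    hbond_strength: 4.5, hbond_r0: 2.9}
  "O-":  {charge: -1.00, lj_epsilon: 0.060, lj_sigma: 3.12, hbond_role: acceptor, hbond_strength: 4.5, hbond_r0: 2.9}
  BOTH:  {charge:  0.00, lj_epsilon: 0.000, lj_sigma: 1.00, hbond_role: none,     hbond_strength: 0.0, hbond_r0: 2.9,
          components: [OH2, DRY]}

# Per-element Lennard-Jones parameters for ligand atoms (epsilon kcal/mol,
# sigma A; sigma = x_vdw / 2^(1/6) from the UFF van der Waals distances).
atoms:
  H:  {lj_epsilon: 0.044, lj_sigma: 2.571}
  C:  {lj_epsilon: 0.105, lj_sigma: 3.431}
  N:  {lj_epsilon: 0.069, lj_sigma: 3.261}
  O:  {lj_epsilon: 0.060, lj_sigma: 3.118}
  F:  {lj_epsilon: 0.050, lj_sigma: 2.997}
  P:  {lj_epsilon: 0.305, lj_sigma: 3.695}
  S:  {lj_epsilon: 0.274, lj_sigma: 3.595}
  Cl: {lj_epsilon: 0.227, lj_sigma: 3.516}
  Br: {lj_epsilon: 0.251, lj_sigma: 3.732}
  I:  {lj_epsilon: 0.339, lj_sigma: 4.009}
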