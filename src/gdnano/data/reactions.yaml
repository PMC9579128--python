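# Reaction channels: plateau cross-sections (barns) above threshold.
# Q-values (MeV) are standard nuclear-data constants and may be overridden.
# The fluorine channel is 19F(p,alpha)16O; 19F is the only stable fluorine
# isotope.
c12_p_3alpha:
  projectile: p
  target_nuclide: C
  products: [alpha, alpha, alpha, p]
  sigma_barn: 0.400
  alpha_multiplicity: 3
  q_value_mev: -7.275
f19_p_alpha:
  projectile: p
  target_nuclide: F
  products: [alpha, O16]
  sigma_barn: 0.500
  alpha_multiplicity: 1
  q_value_mev: 8.114
gd157_n_capture:
  projectile: n
  target_nuclide: Gd
  products: [gamma, Gd158]
  sigma_barn: 250000.0
  alpha_multiplicity: 0
  q_value_mev: 7.937
b10_n_capture:
  projectile: n
  target_nuclide: B10
  products: [alpha, Li7]
  sigma_barn: 4000.0
  alpha_multiplicity: 1
  q_value_mev: 2.790
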