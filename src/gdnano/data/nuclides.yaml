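# Per-element/nuclide constants.
# atomic_mass: g/mol (Gd is taken as pure 157Gd at 157 g/mol).
# A: mass number used for elastic-scattering energy loss.
# sigma_s: epithermal elastic scattering cross-section plateau (barns).
# sigma_c_thermal: capture cross-section at 0.0253 eV (barns), scaled 1/v.
H:   {atomic_mass: 1.008,     A: 1,   sigma_s: 20.5, sigma_c_thermal: 0.332}
C:   {atomic_mass: 12.011,    A: 12,  sigma_s: 4.7,  sigma_c_thermal: 0.0035}
O:   {atomic_mass: 15.999,    A: 16,  sigma_s: 3.8,  sigma_c_thermal: 0.00019}
F:   {atomic_mass: 18.998403, A: 19,  sigma_s: 3.6,  sigma_c_thermal: 0.0096}
Gd:  {atomic_mass: 157.0,     A: 157, sigma_s: 6.0,  sigma_c_thermal: 250000.0}
B10: {atomic_mass: 10.013,    A: 10,  sigma_s: 2.1,  sigma_c_thermal: 4000.0}
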