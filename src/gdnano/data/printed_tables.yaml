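# Published reference values consumed as inputs: calibration targets for the
# synthetic-spectrum generator and operands for the enhancement/reduction
# arithmetic. Doses in Gy per incident proton; strand breaks per incident
# proton; neutron fluences per incident proton integrated thermal-1 keV.
dose_gy_per_proton:
  none: 7.0e-9
  C: 1.5e-8
  GdF4: 1.4e-8
ssb_per_proton:
  none: 2.1e+4
  C: 4.7e+4
  GdF4: 4.0e+4
dsb_per_proton:
  none: 8.8e+3
  C: 1.92e+4
  GdF4: 1.7e+4
neutron_fluence_per_proton:
  healthy:
    without_gd: 4.0e-7
    with_gd: 2.0e-7
  tumor:
    without_gd: 2.0e-6
    with_gd: 3.0e-7
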