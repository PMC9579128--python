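# Material compositions by mass fraction and bulk density (g/cm^3).
# "tissue" is the soft-tissue surrogate (H/O/C) used for both the irradiated
# micro-volume and the macroscopic slab; "Gd" denotes isotopically enriched
# gadolinium-157 throughout.
tissue:
  density: 1.1
  composition: {H: 0.10, O: 0.70, C: 0.20}
carbon:
  density: 2.2
  composition: {C: 1.0}
gdf4:
  density: 7.1
  composition: {Gd: 0.68, F: 0.32}
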