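# Calibrated synthetic-spectrum recipe (regenerated by analysis/03_calibrate_synthetic.py).
baseline:
  k: 2.2
  scale: 333.3460039371252
  theta: 1.6
emax: 15.0
excess:
  C:
    peak: 2.147187490890958
    scale: 371.3572663463572
    skew: 2.377733434147453
  GdF4:
    peak: 1.5640766844179856
    scale: 355.6125799303422
    skew: 0.5000000000000001
excess_band:
- 1.0
- 6.0
n_protons: 100000000
nbins: 15
seed: 0
tolerance: 0.02
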