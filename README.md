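# gdnano

Desk-scale analysis pipeline for **proton-targeted therapy with ¹⁵⁷Gd-doped
carbon and ¹⁵⁷GdF₄ nano-targets**: how much do 50 nm nano-targets boost the
secondary-alpha dose and DNA damage in a tumor irradiated by a clinical
proton beam, and how strongly does the ¹⁵⁷Gd payload suppress the secondary
thermal-neutron fluence?

It is written for radiotherapy-physics researchers who want the full chain —
spread-out Bragg peak (SOBP) beam, nano-target reaction yields, LET-weighted
dose, strand-break totals, neutron capture — as small, tested, seedable
Python instead of a Monte-Carlo transport deck.

## The model in brief

A 50–60 MeV SOBP covers a 1 cm tumor at 2–3 cm depth; the in-tumor proton
spectrum (thermal to ~32 MeV) drives alpha production via

    ¹²C(p,3α)p   (400 mb)      ¹⁹F(p,α)¹⁶O   (500 mb)

at a 50 nm C or GdF₄ nano-target in front of a 0.5 µm tissue cube. The two
effectiveness metrics are spectrum-weighted sums over 1 MeV energy bins,

    Dose_tot = Σᵢ fluence(Eᵢ) · LET(Eᵢ) · 1.6×10⁻¹³   [Gy/proton]
    SSB_tot  = Σᵢ fluence(Eᵢ) · SSB(Eᵢ),   DSB_tot = Σᵢ fluence(Eᵢ) · DSB(Eᵢ)

with LET(E) and RBE(LET) from a shipped 1–12 MeV lookup table and per-alpha
SSB/DSB yield curves peaking at 2 and 1 MeV. Agent effect is reported as
enhancement % = 100·(with − without)/without. Separately, a multigroup
neutron slowing-down model evaluates capture competition when 3000 ppm of
¹⁵⁷Gd (σ_th = 250 000 b, 1/v) is loaded into the tumor at a 70:1
tumor-to-healthy partition. A calibrated synthetic-spectrum generator
stands in for full transport output; see `docs/methods.md` for every model,
assumption and fidelity gap.

## Worked example

```bash
python analysis/01_beam_and_tumor_spectrum.py
```

    range anchors: R(50 MeV) = 2.18 cm, R(60 MeV) = 3.00 cm
    SOBP flat region [2.18, 2.95] cm, flatness 2.1%
    in-tumor proton fluence: 0.757 per incident proton
    spectrum support: up to 33 MeV

The 11-peak SOBP is flat to 2% over the depths its pristine peaks can
reach, and the proton spectrum inside the tumor is capped at ~32 MeV by the
residual energy of the deepest-ranging beam.

```bash
python analysis/04_dose_damage_tables.py
```

    --- agent C ---
       agent  dose_gy_per_proton  enhancement_pct
    No agent        7.000028e-09              0.0
           C        1.499996e-08            114.0
       agent  ssb_per_proton  ssb_enhancement_pct  dsb_per_proton  dsb_enhancement_pct
    No agent    21000.035815                  0.0     8800.067046                  0.0
           C    46999.977135                124.0    19199.962469                118.0

One carbon nano-target roughly doubles the alpha dose (7.0→15.0 nGy per
proton, +114%) and raises SSB/DSB counts by 124%/118%; the GdF₄ run gives
+100% dose. Values are per incident proton, computed from the calibrated
synthetic spectra with Poisson noise at 10⁸ emulated protons.

```bash
python analysis/05_neutron_reduction.py
```

     region      without         with  reduction_percent   factor
    healthy 4.000000e-07 2.243976e-07          43.900590 1.782550
      tumor 2.000000e-06 8.376512e-07          58.117439 2.387629

Thermal–1 keV neutron fluence per proton with 3000 ppm ¹⁵⁷Gd: the slab
model suppresses the tumor fluence more strongly than the healthy-tissue
fluence (58% vs 44%), monotonically up to 6000 ppm; within the 0–0.5 eV
thermal group alone the tumor suppression exceeds two orders of magnitude.

`analysis/02_nano_target_alpha_spectra.py` runs the forced-interaction
Monte Carlo at the nano-target (for carbon, ~61% of the excess alphas fall
in the high-LET 1–6 MeV band), and `analysis/03_calibrate_synthetic.py`
refits and rewrites the shipped calibration fixtures.

A `gdnano` CLI exposes the same stages (`beam`, `micro`, `dose`, `damage`,
`neutron`, `synth`, `run`, `report`); try `gdnano run --out results/run`.

## Layout

    src/gdnano/        library: physics_tables, spectrum, beam_transport,
                       nano_interaction, dose_damage, neutron_model,
                       synthetic_data, pipeline, cli (+ data/ fixtures)
    analysis/          numbered narrative drivers writing results/
    tests/             pytest suite incl. end-to-end acceptance checks
    scripts/           acceptance.py
    docs/methods.md    models, assumptions, calibration, limitations
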