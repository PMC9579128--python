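# Methods

`gdnano` is a desk-scale re-analysis of a proton-targeted-therapy concept:
placing ¹⁵⁷Gd-doped carbon or ¹⁵⁷GdF₄ nano-targets in tumor tissue to (a)
boost the yield of high-LET secondary alpha particles, and (b) soak up
secondary thermal neutrons through the enormous ¹⁵⁷Gd(n,γ) cross-section.
The concept was originally evaluated with full Monte-Carlo transport (10⁸
histories); this package replaces transport with simplified, testable physics plus a
calibrated synthetic-spectrum generator, so the whole analysis runs in
seconds on one CPU. This note records the models, their assumptions, the
parameters that matter, and the known fidelity gaps.

## Beam transport

**Range–energy model.** Proton range in the tissue surrogate
(H 10% / O 70% / C 20%, ρ = 1.1 g/cm³) follows a power law R = αE^p. The
scenario pins three quantities at once: a 50 MeV beam peaking near 2 cm, a
60 MeV beam peaking at 3 cm (the tumor window), and an in-tumor spectrum
extending to ~32 MeV. No power law satisfies all three — fitting the two
range anchors exactly forces p ≈ 2.22 and pushes the residual-energy cap to
36.6 MeV. We anchor R(60 MeV) = 3.0 cm with the near-physical exponent
p = 1.75, giving R(50) = 2.18 cm and a 32.0 MeV residual-energy cap at
2 cm depth: the distal edge and the spectrum cap are honored exactly, the
proximal anchor to within 9%. Both α and p are overridable
(`RangeModel`). Ranges in other materials scale inversely with density.

**Pristine peaks and the SOBP.** Depth dose is the analytic stopping power
S(d;R) ∝ (R−d)^(1/p−1) of the slowing proton convolved with Gaussian range
straggling (σ = 1.2% of range, typical of tens-of-MeV protons in water-like
media; configurable). A spread-out Bragg peak uses n = 11 peaks at 1 MeV
spacing over 50–60 MeV; weights come from nonnegative least squares against
a flat target. Because the allowed peak energies reach only depths
[R(50), R(60)] = [2.18, 3.0] cm, the dose cannot be flat over the entire
2–3 cm window: `build_sobp` flattens over the *peak-covered flat region*
[2.18, 2.95] cm (achieved flatness ≈ 2%, tolerance 5%); the proximal
0.18 cm margin receives 75–100% of the plateau and the last ~0.5 mm sits
on the distal falloff. This is a structural property of the scenario, not
of the optimizer.

**In-tumor spectrum.** Protons sample a peak (by SOBP weight) and a depth
(uniform over the tumor window); the residual energy follows from range
inversion plus a 2% Gaussian energy straggle. The spectrum is binned in
1 MeV bins over 0–33 MeV; the sub-percent tail straggling pushes above
33 MeV is dropped (warned if > 1%). Default 10⁵ sampled protons — spectra
are smooth at that size and the suite stays fast; all stochastic stages
take an explicit seed and are bitwise reproducible.

## Nano-target alpha production

The 50 nm nano-target cube sits in front of a 0.5 µm tissue cube. Two
charged-particle channels are modelled with plateau cross-sections:
¹²C(p,3α)p at 400 mb (Q = −7.275 MeV, threshold 7.89 MeV) and
¹⁹F(p,α)¹⁶O at 500 mb (Q = +8.114 MeV). The "without target" background is
the same carbon channel acting on the 20%-by-mass carbon of the tissue
cube; oxygen alpha channels are omitted (no cross-section is specified for
them). Thin-target interaction probabilities P = nσt are ~2×10⁻⁷ per
proton, so spectra use forced-interaction weighting: every sampled proton
is forced to interact in every channel and carries P as a statistical
weight. This reproduces the expected yields exactly (checked against a
deterministic integral oracle) without 10⁸-history statistics.

Kinematics are non-relativistic with atomic masses. The two-body channel is
the closed-form CM solution, isotropic in the CM. The 3α+p final state is
drawn uniformly from momentum phase space: Gaussian momenta q_i = √m_i g_i
projected onto the zero-total-momentum shell and rescaled to the available
energy — the exact microcanonical measure, with the closed-form check
⟨T_i⟩ = T_cm(1 − m_i/M)/(N−1). The available CM energy is defined so total
product kinetic energy equals E_p + Q *exactly*; since rest mass changes in
a Q ≠ 0 reaction, momentum then closes only to O(Q/Mc²) relative — an
explicit choice, as downstream integrals consume energies, not momenta.
Alpha transport out of the 50 nm film is lossless (film ≪ alpha range).

Known gap: the ground-state two-body kinematics gives ~20 MeV alphas from
fluorine at in-tumor proton energies, above the 0–15 MeV analysis band, so
the Monte-Carlo 1–6 MeV excess property holds for the carbon target; the
1–6 MeV excess for *both* agents is a feature of the calibrated synthetic
spectra (below), which stand in for the full-transport spectra.

## Dose and strand-break integration

Dose_tot = Σ_i fluence(E_i)·LET(E_i)·1.6×10⁻¹³ Gy/proton, and
SSB/DSB totals are the analogous sums over per-alpha yield tables. LET(E)
and RBE(LET) (10% survival) come from a shipped 1–12 MeV lookup table;
interpolation is linear (the grid is dense and smooth) and out-of-range
energies clamp to the end values with a warning. Integrands are evaluated
at bin centers — with 1 MeV bins the difference from bin averaging is
small. RBE is exposed for reporting only; no RBE-weighted dose is computed.

The source units leave fluence unspecified; we take it as "alphas per
incident proton per bin" and apply the 1.6×10⁻¹³ constant verbatim, folding
the implied area/mass normalization into the calibrated spectrum scale.
Absolute per-proton fluences are therefore *calibration products*, not
predictions; enhancement percentages are scale-invariant and unaffected.

The per-alpha damage-yield table is a skewed-peak parametric curve
(E/E_p)^a·exp(a(1−E/E_p)) with the SSB maximum pinned at 2 MeV and the DSB
maximum at 1 MeV; the two scale factors are fitted once so the no-agent
spectrum reproduces the published 2.1×10⁴ SSB and 8.8×10³ DSB per proton.
The fitted table ships as `data/damage_yield.tsv` and regenerates
bit-identically from `analysis/03_calibrate_synthetic.py`.

Enhancement = 100·(with−without)/without, rounded nearest-integer by
default; a nearest-ten and a two-significant-figure policy exist because
the published tables mix conventions. The published tables are internally
inconsistent in two cells (carbon dose enhancement printed as 110% while
its raw doses give 114%; GdF₄ SSB printed as 100% while its raw values give
~91%): the pipeline always reports the value computed from the raw numbers
and leaves the printed percentage to the reader.

## Synthetic spectra and calibration

The generator emulates the *statistical structure* of the transport output:
a smooth gamma-shaped baseline alpha spectrum over 0–15 MeV plus an
agent-specific skewed-peak excess concentrated at 1–6 MeV, with Poisson
noise on raw counts at n = 10⁸ emulated protons (the original event count).
Calibration is deterministic and layered: the baseline fluence scale is an
exact 1-D solve against the no-agent dose (7×10⁻⁹ Gy/proton); the SSB/DSB
yield scales are exact solves against the no-agent strand-break totals;
each agent's excess (scale, peak position, skew) is a bounded least-squares
fit to its three published raw values. Achieved residuals: carbon exact to
machine precision, GdF₄ ≤ 0.14%, all within the declared 2% tolerance;
calibration fails loudly naming the worst residual otherwise, and
recalibrating a calibrated recipe is a no-op. Targets are always the raw
published values, never rounded percentages.

What passing these checks shows: the integration, enhancement arithmetic
and calibration machinery are correct and self-consistent. What it does not
show: that a full transport simulation would produce these spectra — their
absolute scale and shape are anchored to the published tables by
construction.

## Neutron slowing-down and capture

A 1-D slab (tissue 2 cm | tumor 1 cm | tissue 2 cm) is irradiated by an
evaporation-spectrum fast-neutron source, f(E) ∝ E·e^(−E/T) with T = 1.5 MeV
(mean 3 MeV), yield 0.2 neutrons/proton (≈ the inelastic-interaction
fraction of stopping protons; both configurable), born uniformly along the
beam path, emitted half forward / half backward. Transport is multigroup
(8 groups, 10 MeV → thermal; thermal group 0–0.5 eV, representative energy
0.0253 eV) straight-ahead marching: per layer the group-coupling operator
(capture removal + downscatter via the flat-in-outgoing-energy s-wave
kernel, hydrogen-dominated) is exponentiated exactly, so a single purely
absorbing group is exact Beer–Lambert attenuation and capture-free runs
conserve neutron number to round-off.

Thermal neutrons random-walk for tens of cm before absorption, which a
single straight-ahead pass cannot represent; the reported thermal-group
flux per region is therefore the local-equilibrium estimate
Q_th/Σ_a — thermalization rate over macroscopic absorption — which captures
exactly the competition the analysis is about: adding ¹⁵⁷Gd (250 000 b
thermal, 1/v scaled, 157 g/mol, ppm by mass, partitioned 70:1
tumor:healthy) multiplies Σ_a and divides the thermal flux. ¹⁰B (4000 b)
is available as a comparison absorber; the thermal capture-rate ratio at
equal number density is 62.5 by construction.

This is the major fidelity gap relative to full transport: absolute
fluences are not predictive, so the without-Gd baseline is anchored per
region to the published per-proton fluences (2.0×10⁻⁶ tumor, 4×10⁻⁷
healthy) and the with-Gd result applies the *model's* per-group attenuation
ratios to that baseline. The model reproduces the qualitative claims —
suppression is monotone in ppm up to 6000 ppm and the tumor reduction
exceeds the healthy-tissue reduction at 70:1 partition (thermal group alone:
>100× in tumor) — but its integrated thermal–1 keV reduction (≈58% tumor,
≈44% healthy at 3000 ppm) is milder than the published factors, mostly
because the epithermal groups, which dominate the 0.5 eV–1 keV integral,
see the 1/v-suppressed Gd cross-section. The published-value reductions
(50% healthy, factor ≈6.7 tumor) are reported by the arithmetic layer
directly from the published fluences; note that the published in-tumor
fluences imply a factor of ≈6.7, milder than the order-of-magnitude
suppression sometimes quoted alongside them.

## Numerical choices and degenerate inputs

- Interpolation: linear everywhere; exact at grid points (asserted).
- Clamping: LET, RBE and damage yields clamp outside their grids with a
  warning; energies ≤ 0 are errors, not clamps.
- Thresholds: endothermic channels return zero cross-section below the
  non-relativistic lab threshold −Q/(1 − m_p·M_out/M_in²).
- Degenerate SOBP (n_peaks = 1) returns the single distal peak with weight
  1 and no optimization.
- Zero-thickness targets give zero interaction probability; the thin-target
  assertion trips if P ≥ 10⁻².
- Marching step 0.02 cm; flux integrals are trapezoidal, boundary currents
  exact.
- All randomness flows through `numpy.random.default_rng` seeded per stage;
  identical seeds give bitwise-identical outputs.

## Problem sizes

Default run sizes — 10⁵ sampled protons for beam/Monte-Carlo stages,
2×10⁴–10⁵ neutron source samples, 10⁸ *emulated* protons for the Poisson
noise of synthetic spectra — were chosen so the full suite and the
acceptance run complete in well under a minute while keeping counting
errors far below the 2% calibration tolerance. All are configurable.
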