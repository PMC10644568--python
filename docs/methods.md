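# Methods

`etmpheno` re-implements, as a tested pipeline, a multimodal
electro-thermo-mechanical (ETM) phenotyping analysis of breast biopsy
tissue: raw impedance / thermal / mechanical curves are reduced to four
biophysical features per sample, the three tissue groups — adjacent normal
(AN), fibroadenoma (FA, benign), invasive ductal carcinoma (CA, malignant)
— are compared feature-by-feature and with Fisher-combined subsets, and a
Gaussian-process classifier is scored by leave-one-out RMSE.  The bundled
data are the published per-subject feature values (14 subjects, paired
AN + tumour records: 14 AN, 10 CA, 4 FA).  Raw instrument data are not
public, so every stage that consumes raw curves is exercised on synthetic
bundles from this package's generator.

## Feature extraction

* **Z (ohm)** — impedance magnitude at 15 kHz, obtained by linear
  interpolation of |Z| in log-frequency on the 10 Hz – 3 MHz sweep.
* **K (W m⁻¹ K⁻¹)** — 1-D steady-state Fourier conduction at the terminal
  37 °C heating step: `K = P·d / (A·ΔT)`, with heater power `P`, sample
  thickness `d` and cross-section `A` (default 4 mm cube: d = 4 mm,
  A = 16 mm²), and `ΔT` the source–sense temperature difference.  The
  sense temperature comes from a linear platinum-RTD law
  `r = R₀(1 + αT)` (defaults R₀ = 100 Ω, α = 3.85·10⁻³ K⁻¹; the quadratic
  Callendar–Van Dusen term is negligible below 40 °C).  All heater power is
  assumed to pass through the sample; any constant partition factor
  rescales K identically across groups and cancels from every group
  comparison.
* **k (kN m⁻¹)** — stiffness, the ordinary least-squares slope of force
  (mN) vs displacement (µm) over the 18–22 % strain window (strain =
  indentation depth / sample height; mN/µm ≡ kN/m).  A finite window is
  used instead of a point derivative for noise robustness; the width is
  configurable.
* **%R** — percentage relaxation of the normalized load after a 150 s
  constant-displacement hold: `%R = 100·(1 − F_n(150 s))`, with linear
  interpolation if 150 s is not sampled.

Each extractor is the exact inverse of the corresponding generator at zero
noise, which is what the round-trip test suite leans on.

## Equivalent-circuit model

Tissue–electrode spectra follow a Cole-type lumped circuit: extracellular
resistance `R_e` in parallel with `R_i + R_m/(1 + jωR_mC_m)` (intracellular
resistance in series with a leaky membrane), plus `2/(jωC_dl)` for the two
series double-layer interfaces:

```
Z(ω) = 2/(jωC_dl) + R_e ∥ (R_i + R_m/(1 + jωR_mC_m))
```

The two interface capacitances are ideal capacitors (no constant-phase
exponent).  Fitting is weighted complex least squares — magnitude and phase
jointly through the complex impedance, each point weighted 1/|Z| — in
log-parameter space, multi-started (the init plus four seeded log-uniform
perturbations) within ±3 decades of the init.

**Identifiability and gauge fixing.**  The tissue core is a bilinear
function of jω: three degrees of freedom (low-frequency plateau `R0`,
high-frequency plateau `Rinf`, dispersion time constant `τ`) for four
elements.  A one-dimensional continuum of positive `(R_e, R_i, R_m, C_m)`
therefore produces *identical* spectra, and no fitter can recover the
individual elements from data alone.  The package resolves this explicitly:
after optimization the solution is slid along the flat manifold to the
unique member whose ratio `R_i/R_e` equals that of the initial guess.  The
data cannot constrain this ratio, so it is inherited from the init — fits
are initialized from group-nominal element values (standard practice in
impedance analysis), and a fit started from a uniformly rescaled version of
the true elements recovers them exactly.  Reported cohort element means are
meaningful *relative to this convention*; the identifiable quantities
`(C_dl, R0, Rinf, τ)` are convention-free and exposed separately.  For
FA-like tissue (`R_m ≫ R_e`) the membrane resistance enters the spectrum
only as a sub-percent correction to `R0` and is practically unidentifiable;
its fitted value is essentially the prior.

Remaining ties between equal-cost multi-start solutions (within 1e-9
relative) are broken toward the solution closest to the init in log space,
making fits deterministic.

## Group statistics

* **Summaries** use mean ± SEM with the **population-SD convention**
  (divide by n, not n−1).  This is pinned by reproduction: it reproduces
  every published ± value exactly, while the sample-SD convention does not
  (e.g. 3529 instead of the published 3400.7 for AN impedance).
* **Normality gate**: Shapiro–Wilk per group × feature (valid for
  3 ≤ n ≤ 50), warn-only.  All 12 bundled vectors pass at α = 0.05.
* **Two-sample tests**: Welch's unequal-variance t-test, two-tailed, for
  Z, K and k.  A reproduction finding: the published %R comparisons do
  *not* match Welch on the bundled data but match the pooled-variance
  Student t exactly (2.30e-4 / 2.15e-3 / 7.86e-2 vs the published
  2.3e-4 / 2.2e-3 / 7.9e-2, where Welch gives 3.1e-2 / 3.8e-3 / 1.7e-1) —
  evidently the original %R tests were run without the unequal-variance
  correction.  `comparison_matrix` therefore defaults to this
  published-table convention (Welch for Z/K/k, pooled for %R) and offers
  `convention="welch"` for a uniformly Welch analysis.
* **Fisher's combined probability** over each of the 15 non-empty feature
  subsets and 3 group pairs: `X² = −2Σ ln pᵢ ~ χ²(2m)`, using the
  *unrounded* member p-values.  With the convention above, all 45 entries
  agree with the published table within 5 % (half a unit in the second
  significant figure; the residual gap exists because the original
  combinations were computed from the rounded printed member values) and
  all 45 significance categories (*, **, ***, ns; p ≥ 0.05 is "ns",
  boundaries resolved downward) match exactly.  No multiple-testing
  correction is applied across the 45 entries — faithful to the original
  analysis; a caveat, since the entries are strongly dependent.
* **Independence map**: squared Pearson correlation (≡ R² of the
  least-squares line) per feature pair within each group.  The mechanical
  pair (k, %R) is the least independent (0.48 / 0.64 / 0.008 for
  AN / FA / CA); the thermal–relaxation pair reaches only 0.09 in the AN
  group; the FA group has the largest within-group correlations overall.

## Gaussian-process classification

Group labels are encoded **AN = 1, CA = 2, FA = 3** — alphabetical category
order — and a GP *regressor* predicts the continuous label; LOOCV RMSE is
the figure of merit and classes decode by nearest integer (exact halves
round down, clipped to [1, 3]).  This encoding is pinned by reproduction:
it recovers the published single-feature RMSEs to within ~3 % (thermal
0.445 vs 0.4442, stiffness 0.430 vs 0.4286, relaxation 0.596 vs 0.5914,
impedance 0.711 vs 0.6932), whereas the AN/FA/CA → 1/2/3 ordering is far
off for the relaxation feature (0.87 vs 0.5914).

Four covariance kernels are supported — squared exponential, exponential,
Matérn 5/2, rational quadratic — each with signal variance, one isotropic
length scale (features are z-scored per training fold; no ARD) and an
additive noise variance.  Hyperparameters are refit in each fold by
maximizing the log marginal likelihood from a fixed init (noise variance
initialized at half the label variance) plus two seeded random restarts;
the multi-start seed is a pinned design constant so results carry no
run-to-run jitter.  The GP machinery is scikit-learn's; a closed-form
`kernel_eval` is kept as an independent implementation and cross-checked
against it in the tests.

The all-feature Matérn-5/2 RMSE comes out at 0.29 — below every
single-feature RMSE and below 0.45, qualitatively matching the published
picture (their printed 0.2419 depends on unpublished hyperparameter-search
details and is not a target).

## Synthetic-data generator

Defaults *are* the study conditions: per-group feature means from the
bundled table with SD = SEM·√n, sampled log-normally (positivity); cohort
shape 14/4/10.  Per sample the circuit elements are drawn log-normally
around the published group values (inter-subject CV 0.10, a stand-in — only
fit SEs are published) and rescaled uniformly (R × s, C / s) so the
noise-free spectrum passes exactly through the sample's drawn 15 kHz
impedance target; this makes the spectra match both the published feature
distributions and the published circuit-element orderings.  Modality curves:

* loading — `F(δ) = C(e^{βδ} − 1)`, β = 2/height, C set so the slope at
  20 % strain equals the stiffness target; the 30 mN instrument cap
  truncates the sweep but never before 24 % strain (for the stiffest
  samples the modelled load in the measurement window exceeds the cap —
  an accepted artefact of this simple contact model, retained because the
  extractor inverts the same model);
* relaxation — single-exponential with τ = 30 s for all groups (τ is
  unconstrained by the endpoint feature; only the 150 s endpoint is
  pinned, exactly, at the %R target);
* thermal — stepwise source temperatures 25…37 °C in 3 °C steps above a
  20 °C ambient, terminal heater power 5 mW (scaled per step with the
  source-ambient difference, as a controller holding the setpoint would).
  5 mW keeps the sense side 3–7 °C below the source for the published K
  range and above ambient, which is what the sensing geometry requires;
  conductivity draws that would violate this are rejected and redrawn
  (<1 % of draws).  `C_dl = 1e-7 F` (not published; affects only the
  sub-100 Hz region).

Noise defaults (2 % relative |Z|, 1° phase, 0.2 mN force, 0.05 °C RTD,
0.002 normalized load) are placeholders bounded well below the published
6.5 % maximum coefficient of variation for repeat measurements.  With
them, single-sample extraction errors are 0.5–2 % (the 15 kHz read-out of
a 2 %-noisy spectrum is itself ~1.5 % noisy), and recovery is unbiased:
the acceptance suite checks zero-noise inversion exactly and <1 % mean
bias over 20 seeded samples per feature.

What the generator does **not** emulate: electrode polarization beyond the
ideal double layer, frequency-dependent dispersion (no constant-phase
exponent), viscoelastic spectra richer than a single exponential,
heat-loss pathways, instrument drift, or any correlation between a
subject's AN and tumour samples.  Passing round-trip tests therefore
demonstrates internal consistency of extractor + generator under realistic
noise, not instrument-level validity.

## Problem sizes and runtimes

The test suite uses the 28-record bundled cohort for all statistics and GP
checks, 3-per-group synthetic cohorts for pipeline and circuit-ordering
tests, a 200-sample single-group cohort for the law-of-large-numbers
check, and a 50-per-group cohort for the end-to-end recovery check (about
half a minute in total).  `scripts/acceptance.py` re-runs the bundled
statistics, the Matérn-5/2 GP column, the circuit recovery replicates and
a 30-per-group synthetic recovery in ~10 s.  The full 4 × 15 GP table
(`analysis/03_gp_classification.py`) takes about a minute.

## Known limitations

* The per-subject pairing is ignored by the published (and therefore the
  reproduced) unpaired two-group tests; a paired analysis would likely be
  more powerful for AN-vs-tumour contrasts.
* Fisher's method assumes independent member p-values; the features are
  only approximately independent (and the mechanical pair clearly is not),
  so the combined p-values are optimistic.  This mirrors the original
  analysis and is reported as such.
* Circuit elements are only gauge-identifiable (see above); compare
  cohorts via the identifiable quantities where possible.
* With equal synthetic group sizes, the AN–FA combined comparison becomes
  *stronger* than AN–CA — the published ordering between those two pairs
  reflects the benign group's n = 4, not the biophysics.
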