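# etmpheno

Multimodal **electro-thermo-mechanical (ETM) phenotyping** of breast biopsy
tissue: a tested analysis pipeline that distinguishes adjacent-normal (AN),
fibroadenoma (FA, benign) and invasive ductal carcinoma (CA, malignant)
samples from four label-free biophysical features

| feature | definition | units |
|---|---|---|
| Z | impedance magnitude at 15 kHz | Ω |
| K | thermal conductivity at 37 °C, `K = P·d/(A·ΔT)` | W m⁻¹ K⁻¹ |
| k | loading-curve slope at 20 % strain | kN m⁻¹ |
| %R | load relaxation after 150 s, `100·(1 − F_n(150 s))` | % |

It is written for biomedical-instrumentation and biostatistics researchers
who want to reuse or scrutinize the analysis: the per-subject feature table
of the 14-subject study cohort is bundled, every downstream stage is a
library function, and a synthetic-data generator emulating the study
conditions makes the raw-curve stages testable without instrument data.

The pipeline comprises

* **feature extraction** from raw impedance / thermal / mechanical curves;
* a **Cole-type equivalent circuit**
  `Z(ω) = 2/(jωC_dl) + R_e ∥ (R_i + R_m/(1+jωR_mC_m))`
  with a weighted complex least-squares fitter (and an explicit
  gauge-fixing convention for the circuit's structural non-identifiability
  — see `docs/methods.md`);
* **group statistics**: mean ± SEM summaries, Shapiro–Wilk gate, Welch
  t-tests, pairwise R² independence maps, and **Fisher's combined
  probability** `X² = −2Σln pᵢ ~ χ²(2m)` over all 15 feature subsets × 3
  group pairs;
* **Gaussian-process classification** (squared-exponential, exponential,
  Matérn 5/2 and rational-quadratic kernels) scored by leave-one-out
  cross-validation RMSE on numeric labels AN=1, CA=2, FA=3.

## Worked example

```python
from etmpheno import (load_cohort_fixture, summary_table,
                      comparison_matrix, rmse_table)

cohort = load_cohort_fixture()          # 28 records: 14 AN, 10 CA, 4 FA
print(summary_table(cohort).head(3))

cm = comparison_matrix(cohort)          # 45 combined comparisons
for pair in (("AN","FA"), ("AN","CA"), ("FA","CA")):
    p = cm.p(("Z","K","k","%R"), pair)
    print(pair, f"p = {p:.3g}", cm.category(("Z","K","k","%R"), pair))

print(rmse_table(cohort, kernels=("matern52",),
                 subsets=[("Z",),("K",),("k",),("%R",),("Z","K","k","%R")]))
```

prints

```
  group modality   n          mean          sem
0    AN        Z  14  22206.221429  3400.714541
1    AN        K  14      0.449571     0.025353
2    AN        k  14      0.020481     0.002765
('AN', 'FA') p = 1.66e-09 ***
('AN', 'CA') p = 5.61e-13 ***
('FA', 'CA') p = 0.00451 **
                 Z         K         k        %R  Z+K+k+%R
matern52  0.710918  0.445224  0.430334  0.596077  0.289597
```

Reading: no single feature separates all three groups (impedance alone
leaves AN–FA non-significant; the other three leave FA–CA non-significant),
but the Fisher combination of all four separates every pair — benign vs
malignant at p ≈ 4.5e-3 — and the GP classifier's error roughly halves
(0.29 vs 0.43 for the best single feature) when the four modalities are
combined, because they carry largely independent information.

The numbered drivers under `analysis/` run the same stages as narrative
scripts and write their tables to `results/`:

```sh
python analysis/01_cohort_summaries.py     # group means/SEMs, normality gate
python analysis/02_combined_stats.py       # 45-entry comparison matrix, R² maps
python analysis/03_gp_classification.py    # 4 kernels x 15 feature subsets
python analysis/04_synthetic_recovery.py   # generator -> extractor -> circuit fits
```

A thin CLI wraps the same library (`etmpheno simulate | extract | stats |
fit-circuit | classify | run-all`).

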