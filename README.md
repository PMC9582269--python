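# mrkit

Two-sample Mendelian randomization (MR) from GWAS summary statistics,
built for studies that ask whether genetic liability to a behavioural
exposure (for instance cannabis use disorder) causally raises the risk
of binary disease outcomes (coronary artery disease, atrial
fibrillation, heart failure, venous thromboembolism, stroke, ...).
It is a library first — the intended audience is genetic
epidemiologists working in Python who have per-SNP association tables
for an exposure and a set of outcomes and want the complete causal
analysis: instrument selection, harmonization, estimation, pleiotropy
diagnostics, multivariable adjustment, mediation and multiple-testing
control, all reproducible from one seed.

## The model

Each genetic variant *j* gives an independent estimate of the causal
effect through the Wald ratio

```
β̂_j = β̂_out,j / β̂_exp,j ,   se(β̂_j) = se_out,j / |β̂_exp,j| ,
```

and the primary estimator pools them by multiplicative random-effects
inverse-variance weighting,

```
β̂_IVW = Σ w_j β̂_j / Σ w_j ,  w_j = 1/se(β̂_j)² ,
se_IVW = (Σ w_j)^{-1/2} · max(1, √(Q/(k−1))) ,
```

where `Q = Σ w_j (β̂_j − β̂_IVW)²` is Cochran's heterogeneity statistic
(summarised as I² with 25%/50% bands).  For binary traits all betas
are log odds ratios, so `exp(β̂)` is the causal odds ratio per unit of
genetic liability.  Around the IVW estimate the package provides:

- **Instrument selection** — greedy LD clumping (default r² < 0.01 in
  a 10,000 kb window) at a configurable p-value threshold (default
  5×10⁻⁷), per-SNP variance explained
  R² = β²/(β² + N·se²) and F = R²(N−2)/(1−R²), and a-priori power for
  binary outcomes.
- **Harmonization** — effect-allele alignment with strand-flip
  handling, palindromic-SNP policy (drop when the exposure frequency
  is within 0.08 of 0.5) and LD-proxy substitution (r² > 0.60).
- **Sensitivity estimators** — simple and weighted medians
  (parametric-bootstrap SEs; consistent while valid instruments carry
  ≥ 50% of the weight) and MR-Egger regression (intercept = test for
  directional pleiotropy).
- **Robustness** — MR-PRESSO global/outlier/distortion tests with
  simulation-based empirical p-values and outlier-corrected
  re-estimation; leave-one-out analysis with influence flags.
- **Multivariable MR** — direct effects adjusting for a covariate
  exposure (weighted no-intercept regression on both exposures'
  betas), with conditional instrument-strength reporting.
- **Mediation** — product-of-coefficients and difference
  decompositions with delta-method SEs and proportion mediated.
- **FDR control** — Benjamini–Hochberg q-values over the primary IVW
  p-value family.
- **Synthetic GWAS generator** — seeded summary-scale simulation of
  the whole two-sample design (instrument strength guarantees,
  case-fraction variance inflation, balanced/directional pleiotropy),
  so every stage is testable without any data download.

## Worked example

`examples/univariable_mr.py` generates a 12-instrument panel with a
true causal odds ratio of 1.10 and compares the estimators:

```
true OR = 1.1, k = 12 instruments

method                OR            95% CI         p
ivw_mre            1.143    (0.932, 1.401)       0.2
simple_median      1.162    (0.896, 1.508)     0.257
weighted_median    1.156    (0.893, 1.498)     0.272
egger_slope        1.251    (0.530, 2.954)      0.62
```

All four methods bracket the true OR; the Egger interval is widest
because its robustness to directional pleiotropy costs precision at
k = 12.  The other examples cover pleiotropy diagnostics
(`pleiotropy_diagnostics.py`), multivariable MR with mediation
(`mvmr_and_mediation.py`) and the file-based end-to-end pipeline with
forward and reverse directions (`full_pipeline.py`).

A thin CLI mirrors the library for shell use:

```
mrkit simulate --seed 7 --k 12 --theta 0.0953 --outdir data/
mrkit pipeline --config config.yaml --outdir results/
```

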