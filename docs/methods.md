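# Methods

## Setting and assumptions

The package estimates the causal effect of one trait (the exposure) on
another (the outcome) from two independent GWAS summary tables, using
genetic variants as instrumental variables.  Validity rests on the
three instrumental-variable assumptions: each instrument is associated
with the exposure (relevance), independent of confounders of the
exposure–outcome relationship, and affects the outcome only through
the exposure (exclusion restriction).  The estimators differ in how
much exclusion-restriction violation (horizontal pleiotropy) they
tolerate: IVW assumes none on average, the weighted median tolerates
up to half the weight on invalid instruments, MR-Egger tolerates
directional pleiotropy if instrument strength is independent of the
pleiotropic effects (InSIDE).

The two samples are assumed non-overlapping; with overlap, weak
instruments would bias estimates toward the observational association
rather than the null, and nothing in the package detects that.

## Instrument selection

Candidates below the significance threshold (default 5×10⁻⁷, a
"suggestive" cut chosen when genome-wide-significant variants are too
few) are thinned by greedy LD clumping: repeatedly keep the
smallest-p remaining SNP and discard SNPs within `window_kb` (default
10,000 kb) on the same chromosome with r² ≥ `r2_threshold` (default
0.01) against it.  LD comes from a user-supplied pairwise r² table;
pairs absent from it are treated as unlinked with a logged warning,
matching the permissive behaviour of clumping against an incomplete
reference panel.  The window is interpreted pairwise from the current
index SNP.  Ties in p are broken by position, then rsid, so selection
is deterministic.

Per-instrument strength is R² = 2·EAF(1−EAF)β² / (2·EAF(1−EAF)β² +
2·EAF(1−EAF)N·se²) — the allele-frequency factor cancels but the full
form is retained — and F = R²(N−2)/(1−R²).  A-priori power for a
binary outcome uses the non-centrality approximation
λ = N·R²·cf(1−cf)·ln(OR)², power = 1 − Φ(z₁₋α/₂ − √λ) +
Φ(−z₁₋α/₂ − √λ); this is the standard approximation implemented by the
widely used online calculators, and the test suite checks it against a
Monte-Carlo rejection rate.

## Harmonization

Outcome effects are re-expressed on the exposure's effect allele:
identical allele pairs are kept, swapped pairs have the outcome beta
negated and frequency reflected, strand-complement pairs are
complemented first, and anything irreconcilable is dropped with reason
`allele_mismatch` rather than silently kept.  Palindromic SNPs (A/T,
C/G) cannot be strand-resolved from alleles: they are dropped when the
exposure effect-allele frequency lies within 0.08 of 0.5 (window
configurable), dropped unconditionally when the outcome frequency is
missing, and otherwise oriented by frequency agreement.  Instruments
absent from the outcome GWAS are substituted by a user-supplied LD
proxy (r² > 0.60 enforced at load); proxy effect sizes are used as-is,
without attenuation by r², so users wanting attenuation must pre-scale.
Unproxied instruments reduce k and are reported.

## Estimators

Wald ratios use the first-order delta-method SE `se_out/|β_exp|` by
default — matching the convention of the established two-sample MR
software, which keeps desk-scale numbers comparable — with the
second-order form available.  IVW pools ratios with multiplicative
random effects: the fixed-effect SE is inflated by √(Q/(k−1)) floored
at 1, so under-dispersion never shrinks the SE below fixed-effects.
IVW and median p-values use the normal reference; MR-Egger and
multivariable MR use t with k−2 degrees of freedom since their k is
small.  Median estimators take SEs from a parametric bootstrap
(ratio_j* ~ Normal(ratio_j, se_j), default 1,000 replicates, seeded);
the weighted median interpolates the inverse-variance-weighted
empirical CDF at 0.5 and reduces exactly to the simple median under
equal weights.  MR-Egger orients all pairs to positive exposure betas,
regresses outcome betas on exposure betas with an intercept and
weights 1/se_out², and floors its residual scale at 1 like the other
regression estimators.

Multivariable MR regresses outcome betas on two exposures' betas with
no intercept (weights 1/se_out²), reporting the primary exposure's
coefficient as its direct effect.  Models adjust for one covariate at
a time — the reporting unit of adjusted-association tables — rather
than one saturated model.  The joint instrument panel is the union of
the two pre-clumped instrument lists, re-clumped with the same
configuration to break cross-exposure LD (a "primary-instruments-only"
mode is available behind a switch).  Weak-after-conditioning
instruments are not pruned; instead an approximate conditional F per
exposure (heterogeneity of the exposure's betas around their
projection on the other exposure, relative to measurement error,
divided by k−1) is reported for transparency.  A condition-number
check warns on near-collinear exposures and refuses rank-deficient
designs.

Mediation offers both decompositions.  Product: indirect = a·b with
SE √(a²se_b² + b²se_a²), where a is the exposure→mediator estimate
and b the mediator→outcome estimate adjusted for the exposure.
Difference: indirect = total − direct with the independence
approximation SE √(se_total² + se_direct²), flagged explicitly because
two-sample summary data cannot identify the covariance.  Proportions
mediated outside [0, 1] (inconsistent mediation) are reported with a
warning, never truncated.

## Robustness diagnostics

Cochran's Q uses the pooled estimate supplied by the caller; I² =
max(0, (Q−df)/Q)·100 with bands low (≤25%), moderate (25–50%], high
(>50%).  The band definitions found in applied practice overlap at
exactly 50%; the boundary is assigned to "moderate" here, a documented
convention rather than a claim about any source's intent.

MR-PRESSO computes the observed residual sum of squares of each
instrument against its leave-one-out IVW prediction and compares it
with a simulated null in which outcome betas are redrawn around those
predictions at their reported SEs, with leave-one-out slopes
recomputed inside every simulated panel (default 1,000 simulations;
empirical p floored at 1/(nsim+1)).  Per-instrument outlier p-values
use the same construction observation-wise with Bonferroni correction
across instruments, the convention of the reference implementation.
The corrected estimate is IVW on non-outliers; if every instrument is
flagged the correction is refused with an error.  A distortion test
(displacement of the estimate versus removing random same-size
subsets) is computed but labelled exploratory.  The method is designed
for panels larger than 10 instruments; smaller panels get a warning,
not an error.  Leave-one-out flags an instrument as influential when
omitting it changes whether the 95% CI excludes the null.

## Multiple testing and orchestration

Benjamini–Hochberg q-values (via statsmodels) are computed over the
family of primary IVW p-values of one analysis direction — the
per-figure correction unit — with sensitivity methods corrected within
their own family if desired.  Note that BH q-values are not monotone
in family size in general: adding a duplicate of a small p can lower
other q-values because ranks grow faster than m; they are monotone
when the added p is at least the family maximum, and the property
tests assert exactly that.

The pipeline runs selection → harmonization → estimation →
diagnostics → FDR per outcome, optionally the reverse direction (each
outcome as exposure against the original exposure as outcome) and
multivariable/mediation extensions.  A fatal error in one pair is
tabulated as an explicit NA row and the run continues.  All
stochastic stages draw from streams spawned deterministically from one
root seed (`numpy.random.SeedSequence`), so identical configuration
implies byte-identical outputs.

## The synthetic-data generator

Simulation happens directly on the summary scale: per-SNP minor-allele
frequencies are uniform on (0.05, 0.45); exposure SEs are the analytic
1/√(2·maf(1−maf)·N); binary-outcome SEs include the case-fraction
variance inflation 1/√(2·maf(1−maf)·N·cf(1−cf)); observed betas are
the true effects plus independent normal noise at exactly those SEs.
Because the pipeline consumes only summary data, this generative model
is exact for everything the estimators see — no individual-level
simulation is needed, and the SE fields match the formulas to machine
precision by construction.

True exposure effects are Normal(0, γ_scale²) rejection-sampled until
the *true* association reaches p < 5×10⁻⁷ at the exposure sample
size.  Selecting on the true rather than the observed effect makes
every generated SNP a legitimate instrument without winner's-curse
bias; when the pipeline is then run with an observed-p threshold, a
realistic fraction of instruments drops out, as in real re-analysis.
The default γ_scale of 0.015 with 12 instruments at N ≈ 350–384k gives
a total variance explained on the order of 0.1% and minimum F in the
tens — the instrument-strength regime of a large behavioural-exposure
GWAS feeding suggestive-significance instruments into disease
outcomes.

Pleiotropy modes: "none"; "balanced" (zero-mean pleiotropic effects on
a random `frac_invalid` subset, preserving InSIDE and IVW consistency
on average); "directional" (mean-μ effects applied with the sign of
the SNP's exposure effect, i.e. on the exposure-increasing-allele
orientation).  The orientation matters: with sign-symmetric exposure
effects an unsigned pleiotropic shift is balanced on the Wald-ratio
scale, so "directional" pleiotropy would not bias anything, would give
the Egger intercept no power, and could not demonstrate the weighted
median's robustness.  Defining it on the trait-raising orientation
matches how directional pleiotropy is simulated in the MR methods
literature.  The directional test conditions used in the acceptance
checks (μ_α = 0.02, sd_α = 0.005, 40% invalid) put the ratio-scale
contamination on the order of the causal effect itself — strong enough
that IVW is visibly biased while valid instruments still hold a
majority of the median weight.

What the generator does not emulate: LD between instruments (they are
independent by construction, representing a post-clumping panel),
sample overlap, allele-frequency mismatch between studies, population
stratification, and winner's curse in the exposure betas.  Passing
simulation tests therefore demonstrates correctness of the estimators
under the two-sample summary-data model, not robustness to those
real-data pathologies.

## Problem sizes and numerical choices

The simulation studies use 500 replicates for recovery/coverage and
robustness comparisons, 1,000 for type-I error (grouped into 142
seven-outcome families for the FDR check), and 200 runs for outlier
detection with 1,000 PRESSO simulations each — sizes at which the
Monte-Carlo error of each assertion is a small fraction of its
tolerance, chosen as the package's own desk-scale defaults.  Empirical
p-values are computed with the +1 correction so they are never zero.
Bootstrap and PRESSO seeds are mandatory in the orchestrated pipeline
and derived from the root seed.  Floats are written with 17
significant digits so file round-trips are bit-exact; p-values of
exactly 0 on input are replaced by the smallest positive double and
flagged.

## Known limitations

Positions are treated as opaque within one analysis; mixing genome
builds between exposure and outcome files is the user's
responsibility to avoid.  Indel alleles are read but never harmonized.
The difference-method mediation SE ignores the total–direct
covariance (flagged).  MR-Egger's power at k = 12 is low, and the
conditional-F report is an approximation, not the full
generalized-method-of-moments version.  Mode-based estimators,
MR-RAPS, radial MR and Steiger filtering are out of scope.
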