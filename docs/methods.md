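# Methods

This note documents the models, defaults and numerical choices behind
`bodymr`, in the order the pipeline applies them.

## Summary data and harmonization

A summary dataset holds one association per SNP: effect/other allele,
effect-allele frequency (EAF), β (per-allele SD units for continuous
traits, log-OR for disease), SE, p, and per-SNP n. Positions are 1-based
on a single assumed genome build; no liftover is attempted, because the
intended inputs are pre-imputed consortium files released on one build.
Rows violating record invariants are dropped and counted, not fatal —
consortium files routinely contain unusable rows. Two dialect presets
mimic the large anthropometric and AD consortium layouts; the AD-like
dialect has no EAF column, so EAF is optional everywhere downstream.

Harmonization aligns the outcome to the exposure's effect allele:
matching alleles copy, swapped labels negate β and flip EAF, and
incompatible sets are dropped as mismatched (an optional strand-flip step
first complements the outcome alleles when that reconciles them).
Palindromic SNPs (A/T, C/G) cannot be resolved from alleles alone; they
are aligned by EAF agreement when both frequencies are clearly away from
0.5 and dropped as ambiguous otherwise. The ambiguity window is
**0.5 ± 0.08** (drop when either dataset's EAF lies in [0.42, 0.58] or is
missing). The source analyses state only that ambiguous palindromes were
discarded; 0.08 is this package's quantification of "ambiguous" and is a
configurable parameter, not an estimate.

Every requested SNP lands in exactly one report category
(harmonized / ambiguous / mismatched / absent), so nothing is silently
lost.

## Instrument selection

Clumping is greedy: rank genome-wide-significant SNPs (P < 5×10⁻⁸) by
ascending p (rsID breaks ties, making results order-independent), keep
the best, remove neighbours on the same chromosome within 10,000 kb with
r² ≥ 0.001, repeat. A SNP is removed only when it is *both* within the
window and above the r² threshold — the standard clumping semantics; the
two numbers are parameters of one rule, not alternative rules.

Confounder screening removes candidates with r² ≥ 0.5 to any SNP in a
configured confounder list; confounder lists are inputs, not built-ins.
The two-stage workflow re-admits SNPs at stage "additional" by removing
cleared traits (default BMI and WHR) from the confounder configuration.
APOE exclusion removes candidates with r² ≥ 0.1 to rs429358/rs7412 or
inside a configurable window (default chr19:45.0–45.8 Mb) — deliberately
strict, because APOE dominates AD genetics and "unlinked" should be
demonstrable. Proxies require r² > 0.9, presence in both datasets,
non-ambiguity and passing both screens; ties break by higher r², then
smaller exposure p, then rsID.

Instrument strength uses R² = Σ 2f(1−f)β² for a standardized exposure and
**F = R²(n−k−1) / (k(1−R²))**, flagging F ≤ 10. This is the package's
declared formula; published per-trait F values computed with an
unavailable variant are not reproduced by it and are not targeted.

## Estimators

* Wald ratio SE is first-order delta method only (σ_Y/|β_X|): the
  second-order term is negligible for instruments that pass the F screen,
  and this matches the weighting all multi-SNP estimators use.
* IVW defaults to multiplicative random effects (SE inflation by
  max(1, √(Q/(k−1)))); a fixed-effect option exists. With k = 1 IVW
  reduces exactly to the Wald ratio.
* MR-Egger orients instruments to β_X ≥ 0, fits WLS with intercept
  (weights σ_Y⁻²) via statsmodels, and bounds the residual scale below by
  1 so reported precision never exceeds the fixed-effect value.
* Weighted median: ratios ordered ascending, normalized weights
  w = β_X²/σ_Y², estimate interpolated at cumulative standardized weight
  0.5.
* Weighted mode: argmax of a Gaussian-kernel weighted density with the
  modified Silverman bandwidth φ·0.9·min(weighted SD, weighted
  IQR/1.34)·k^(−1/5), φ = 1 by default; a zero bandwidth (all ratios
  equal) returns the common ratio. The density is maximized on a
  512-point grid spanning the ratio range ± 3 bandwidths.
* Weighted-median/mode SEs come from a parametric bootstrap (n_boot =
  1000 by default, explicit seed): β̂_X and β̂_Y are redrawn from their
  normal sampling distributions and the point estimator is recomputed.
* All CIs use the normal quantile 1.959964; p-values are two-sided
  normal.

## Diagnostics

Cochran's Q over Wald ratios at the IVW fit equals the weighted residual
sum of squares of the no-intercept regression (an identity the tests
check to 1e-10); I² = max(0, (Q−df)/Q)·100 with 25/50/75% boundaries, and
H = √(Q/df). The p-value attached to both Q and H is the χ²(k−1) tail of
Q — they test the same homogeneity hypothesis.

The MR-PRESSO-style test computes, for each SNP, the leave-one-out IVW
fit and the weighted squared residual of that SNP against it; the global
statistic is the residual sum. n_sim = 1000 datasets are simulated under
the no-pleiotropy null (β*_Y ~ N(β̂_(−j)β_X, σ_Y), β*_X ~ N(β_X, σ_X)),
giving a global p with the +1 continuity correction. Per-SNP outlier
p-values are raw empirical tail probabilities (no +1), Bonferroni-scaled
by k, flagged at 0.05: with the correction the smallest reachable
adjusted p would be k/(n_sim+1), which exceeds 0.05 for k ≥ 51 and would
make the outlier test vacuous exactly where it is needed. The distortion
test of the original method is not implemented (outliers here are
removed, not re-weighted).

Leave-one-out influence compares each re-fit against the full-set
**fixed-effect** 95% CI. Under the random-effects CI a single gross
outlier inflates the full-set interval in proportion to its own
displacement (the shift-to-CI ratio tends to √((k−1)/k)/1.96 < 1 as the
displacement grows), so the rule could never fire on the one-bad-apple
case it exists to catch. Outlier removal is a single pass — MR-PRESSO
outliers first, then LOO-influential SNPs on the reduced set, then one
re-fit — with every removal logged.

## Power

The binary-outcome approximation treats the causal log-OR estimate as
normal with SE 1/√(N·R²·K(1−K)), K the case fraction of the outcome
GWAS. The detectable-OR inversion keeps only the dominant tail:
ln(OR_min) = (z_{1−α/2} + z_{power})/√(N·R²·K(1−K)), OR_max = 1/OR_min.
The neglected opposite tail is positive and contributes < 0.005 to power
at the 80% target (asserted in the tests). Printed power figures from
calculator variants that differ by ≲1% near 80% are not targeted; the
cells robust to the variant (the minimal detectable OR of 1.19 and the
two >99% entries) are.

## Survivor-bias simulation

The simulation asks whether restricting a case-control sample to
survivors biases the BMI→AD estimate when mortality depends on age and
BMI but AD, by construction, depends on age alone.

Defaults (all configurable; units in parentheses):

| parameter | default | meaning |
|---|---|---|
| n_individuals | 500,000 | population per replicate |
| n_snps / target_r2 | 60 / 0.0214 | instruments, variance explained |
| residual_sd | √(1−R²) | BMI residual SD so total variance is 1 (SD units) |
| bmi_mean / bmi_sd | 25.0 / 4.69 (kg/m²) | maps SD-unit BMI onto the natural scale |
| age | truncated normal, mean 73, sd 8, bounds 55–100 (yr) | AD-study-like age mix |
| λ, a, b | 10⁻³, 3×10⁻⁵, 0.09 (/yr) | Gompertz–Makeham; typical adult-human fits |
| γ₁, γ₂, x_ref | 0, 0.003 (/(kg/m²)²), 22.5 (kg/m²) | log-quadratic U-shaped BMI–mortality effect |
| AD prevalence | (60→1%, 70→4%, 80→12%, 90→30%), linear, clamped | age-specific prevalence |
| n_reps | 1000 | replicates |

Modelling choices worth stating explicitly:

* The full survival model is read as **S(t|x) = S_b(t)^w(x)** — w acts
  multiplicatively on the cumulative hazard, so w ≡ 1 recovers the
  baseline exactly and doubling w squares survival.
* w(x) is the minimal U-shape (log-quadratic around x_ref); both low and
  high BMI raise mortality when γ₂ > 0.
* S(age) is interpreted as the probability of being alive at the
  individual's current age; there is no follow-up time dimension.
* The residual-variance parameterization takes residual_sd = √V_E, with
  V_E the residual phenotypic variance.
* MR inside a replicate is one-sample: per-SNP exposure slopes (OLS of
  BMI on genotype) and outcome log-ORs (logistic of AD on genotype) are
  estimated in the same subset, mirroring a single simulated population.
* The baseline subset is the full population (nobody dies); the survivor
  subset keeps the alive (optionally subsampling controls to a fixed
  control:case ratio). Replicates with fewer than 100 cases are redrawn
  deterministically and counted.
* Per-SNP logistic fits use a count-based 2-parameter Newton solver
  (genotypes take only values 0/1/2, so the likelihood depends on six
  counts per SNP); it is verified against statsmodels Logit to 1e-8 in
  the tests. The master seed spawns per-replicate seeds via
  `numpy.random.SeedSequence`, so runs are bit-reproducible.

Bias is declared per method (observational, IVW, Egger) when the
full-vs-baseline difference of mean estimates exceeds 3 Monte-Carlo SEs;
a Welch two-sample p-value is reported alongside.

## Synthetic summary-data generator

The generator emulates the *shape* of consortium inputs at instrument
scale: k instruments plus decoys and optional confounder-linked SNPs,
EAFs Uniform(0.05, 0.95), exposure SEs 1/√(2f(1−f)n), binary-outcome SEs
1/√(2f(1−f)N·K(1−K)), observed effects drawn around the truth, block LD
(identity by default), and configurable palindromic (10%) and
swapped-allele (10%) rows to keep harmonization honestly exercised. True
per-SNP effects are scaled so Σ2f(1−f)β² equals the target R² exactly,
with per-SNP variance explained made MAF-independent (β ∝ 1/√(2f(1−f)),
spread Uniform(0.8, 1.2)) so that every instrument clears genome-wide
significance at the emulated sample sizes and the configured instrument
count is the count the pipeline analyses. Directional pleiotropy is
injected in the exposure-increasing-allele frame (the frame MR-Egger
fits in), so a constant c shows up as an Egger intercept of c.

What it does **not** emulate: genome-wide SNP counts, realistic LD decay,
MAF-dependent effect-size distributions, population stratification,
sample overlap between the two GWAS, or winner's curse from in-sample
instrument discovery. Passing calibration tests on these fixtures shows
the estimators and pipeline are correct under their stated sampling
model, not that real consortium analyses are free of those
complications.

## Problem sizes used in the checked runs

The statistical acceptance checks run at sizes chosen to make sampling
bands tight while keeping the suite quick: 200 synthetic studies per
condition for pipeline coverage/recovery (bootstrap n_boot = 200 there,
which affects only the bootstrap SEs of the median/mode estimators, not
the IVW quantities being checked); 100 seeds for MR-PRESSO size and
sensitivity (k = 30, n_sim = 1000); and 50,000 individuals × 100
replicates (× 4 master seeds) for the survivor simulation. The headline
configuration (500,000 × 1000) runs identically, just longer.

## Known limitations

* Two-sample estimators assume a linear exposure–outcome relationship on
  the log-OR scale and no sample overlap; the overlap audit quantifies
  but does not correct overlap.
* The weighted-mode bandwidth rule and the LOO influence rule are
  conventions; conclusions sensitive to them warrant sensitivity
  analysis.
* The survivor simulation's mortality and prevalence defaults are
  plausible mid-range values, not fits to a specific cohort; its verdict
  concerns the mechanism, not any particular population.
* LD is consumed as input; the package never computes it from genotype
  panels, and proxy search is limited to SNPs present in the supplied LD
  lookup.
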