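# Methods

This note documents the models behind each pipeline stage, the choices
made where the design was genuinely open, what the synthetic cohorts do
and do not emulate, and the package's numerical conventions.

## Severity phenotyping

ARMSS re-expresses an EDSS measurement as its rank within an
age-matched reference population on a 0–10 scale. The published ARMSS
matrix is not redistributable, so the score is implemented as
age-stratified mid-rank scaling against a *pluggable* reference table
(integer-age bins): `armss(age, edss) = 10 × ½(F≤ + F<)` where `F≤` and
`F<` are the fractions of reference EDSS values at that age that are
`≤` and `<` the observed one. This preserves the score's defining
property — age-relative EDSS rank — and is invariant to duplicating
reference strata. Patients need ≥ 3 relapse-independent EDSS scores and
≥ 5 years of follow-up; the longitudinal score is the median over
relapse-independent visits (even counts average the middle two).

Severity labels use type-7 (linear interpolation) percentiles, with the
"at or below P20 / at or above P80" rule keeping threshold ties. The
percentile method is fixed and documented because different quantile
conventions move boundary samples between labels. If P20 = P80 every
sample would qualify for both labels; the cohort is then labelled
excluded with a warning. Whether percentiles are computed before or
after other exclusions is left to the caller (pass whichever score pool
is wanted); relapse independence is a boolean flag in the visit table —
no relapse-window arithmetic is attempted.

## Preprocessing

Probe removal applies the ≥ 5 %-of-samples failure fraction to both the
detection-p (> 0.01) and bead-count (< 3) channels, plus annotation
flags (non-CpG, SNP-related, multi-hit, non-autosomal). The rules
commute; the report attributes each probe to every rule it violates and
counts unique removals. Sample removal uses failed/passing > 0.1.

Beta values are clipped to [1e-6, 1−1e-6] before the logit so M-values
stay finite; the M-view is a pure function of beta.

**BMIQ-style normalisation.** Per sample, three-state beta mixtures
(unmethylated / hemimethylated / methylated) are fitted by EM to the
type-I and type-II distributions separately (quantile-seeded
responsibilities, method-of-moments shape updates, tolerance 1e-4 on
mean log-likelihood, 100 iterations max). Each type-II value is
assigned to its maximum-posterior state and mapped through the
state-wise quantile transform `F_I⁻¹(F_II(x))`, monotone within each
state; type-I probes pass through. A non-convergent EM leaves that
sample unchanged with a logged warning rather than failing the run.

**Batch effects.** Detection: SVD of the probe-centred M matrix, top 10
right singular vectors tested per factor (one-way ANOVA for
categorical, Pearson for continuous), flagged at p < 0.01. Correction:
parametric ComBat — probe-wise standardisation against the
batch-size-weighted grand mean and pooled variance, per-batch
location/scale estimates shrunk to normal / inverse-gamma priors fitted
across probes by moments, iterative joint solution, adjust and restore.
Only the parametric form is implemented. Note that empirical-Bayes
shrinkage deliberately removes the *shared* component of per-probe
batch effects and leaves the noise-driven remainder; correction is
therefore near-identity, not identity, on batch-free data, and a second
application still moves the matrix slightly. Sequential application
over an ordered factor list is supported for multi-factor designs.

## Differential methylation

The primary test is a per-probe logistic regression of group (severe =
1) on the beta value plus adjustment covariates, defaulting to the NK
cell proportion; the reported p is the Wald p of the methylation
coefficient. A linear mode (M ~ group + covariates) is provided since
both formulations are in common use; the logistic form is the default.
Near-separation makes logistic Wald tests non-monotone (Hauck–Donner),
so separation warnings and exploding coefficients trigger a
ridge-penalised IRLS fallback (λ = 1e-3, intercept unpenalised) whose
Wald p is reported with a "separation" flag. Constant probes get p = 1.

Multiplicity uses hand-rolled Benjamini–Hochberg (validated against
both the literal step-up definition and statsmodels). Filters: FDR
strictly < 0.05 and |Δβ| strictly > 0.01; "major" DMPs have |Δβ|
rounded to 3 dp at or above 0.05 so a printed 0.050 qualifies. Reported
direction is relative to the severe group (positive Δβ =
hypermethylated in severe).

The matched-pair sensitivity analysis pairs mild to severe samples
greedily by nearest age (each sample used once, default ±2-year cap —
the matching algorithm is unspecified in the field's descriptions, so
the simplest deterministic one is used and exposed as config). Per pair
and probe, Δβ = severe − mild; continuous covariates are tested by
Pearson correlation of Δβ against the per-pair covariate difference,
categorical covariates by one-way ANOVA over concordant pairs only, BH
within covariate.

## DMR calling

DMPs passing FDR < 0.01 are sorted by (chromosome, position) and
chained while adjacent gaps are ≤ 1000 bp and signs agree; runs of ≥ 2
emit a region. Width is end − start (matching the published regions'
arithmetic, e.g. 57,664,704 − 57,664,490 = 214). A sign flip splits the
chain at the flip, which preserves the same-direction rule maximally.
`max_delta` is the signed Δβ of the largest-|Δβ| member. The caller is
validated against an exhaustive enumeration oracle.

## Cell-type deconvolution

Reference-based deconvolution replaces support-vector regression with
non-negative constrained least squares renormalised to sum to one: the
downstream analyses need proportion estimates, not SVR machinery, and
CLS is exactly specifiable and testable (noise-free mixtures are
recovered to solver tolerance). Marker probes are chosen per cell type
by largest deviation from the mean of the other types (default
100/type, configurable).

The cell-specific DMP model is the no-intercept interaction design
`M ~ Σ_k w_k + Σ_k (w_k × severity)`: because proportions sum to one,
the proportion columns span the intercept, the design is full-rank
without dropping a reference cell type, and every type keeps its own
interaction Wald test (dropping the largest type would have silently
lost its csDMP test). Significance uses the genome-wide threshold
p ≤ 9×10⁻⁸, inclusive. Constant-proportion designs are flagged
collinear rather than fitted.

## mQTL analysis

Genotype QC order: call rate < 95 %, MAF < 0.05 (strict), HWE p < 1e-5
(1-df chi-square; exact conditional test when an expected count is
below 5), monomorphism, non-autosomal; then samples at call rate
< 95 %. The ±5 kb cis window is inclusive at the boundary. LD pruning
keeps SNVs greedily in MAF-descending order, discarding any whose
genotype correlation test against an already-kept SNV has p < 0.05.
Methylation–genotype association uses tie-corrected Kruskal–Wallis
(beta values are not normal); the genotype-adjusted model is a joint
logistic regression of severity on methylation and genotype, with the
ridge fallback under separation. Only hard genotype calls are accepted;
a dosage-to-call threshold of 0.9 applies if dosages are supplied.

## Methylation age

Clocks are linear predictors over clock CpGs with an optional monotone
linear calibration; coefficient tables load from TSV so published
clocks can be plugged in without bundling their coefficients (tests use
the generator's synthetic clock with known truth). ≥ 90 % of clock CpGs
must be present; missing ones are imputed with the cohort mean beta of
the present clock CpGs (standard clock practice). MAA is the residual
of regressing chronological age *on* the clock estimate — the direction
used in the severity-EWAS literature this mirrors — with the
conventional direction (clock on chronological) behind a flag; with
this default, a biologically older group shows *negative* residuals, so
group differences are reported with their absolute value alongside the
sign convention. Group comparison is a t-test when Shapiro–Wilk keeps
normality (p > 0.05), Wilcoxon rank-sum otherwise; pack-year style
smoking surrogates always use the rank-based branch.

## Classification

The 70:30 split is stratified by severity (an unstratified flag is
deliberately absent — stratification is the safer default and the
split sizes match either way): the pooled training size floor(0.7·n) is
allocated across strata by largest remainder, reproducing both
235 → 164/71 and 10 → 7/3.

The elastic net uses the glmnet parametrisation — mean logistic
deviance + λ(α‖β‖₁ + (1−α)/2‖β‖₂²) on internally standardised features,
coefficients reported on the original scale — solved by scikit-learn's
saga solver (C = 1/(nλ), l1_ratio = α). Tuning runs k-fold CV (stratified
folds) over an alpha grid and a geometric lambda path from the
data-driven λ_max down two decades, warm-starting along each fold's
path; the (α, λ) pair minimising mean held-out deviance wins, ties to
the larger λ. Variable importance is 100·|standardised coefficient| /
max. When every coefficient is zero the intercept is set analytically
to the prevalence log-odds. Published (α, λ) values can be passed as
overrides but are never defaults.

The wMRS standardises discovery-DMP beta values with *training-set*
means/SDs and weights the z-scores by discovery Δβ; test samples reuse
the training constants (leakage prevention), and `compare_models`
raises on any train/test overlap. ROC AUC is the normalised
Mann–Whitney statistic (ties count half), validated against all-pairs
counting.

## Synthetic cohorts

Construction: six leukocyte reference profiles (bimodal probe means;
type-specific marker probes flipped to the opposite methylation mode,
capped at half the array) are mixed with Dirichlet weights
(concentration (6, 4, 3, 2, 3, 12) — granulocyte-dominated blood);
severity effects are added to the mixed signal on the beta scale
(default effect sizes 1–14 %, spanning the range such studies report);
the matrix moves to the M scale where cis-mQTL shifts (0.5 M per
allele), optional batch location/scale effects and Gaussian noise
apply; the inverse logit returns beta values strictly inside (0, 1)
without truncation. Default noise is SD 0.3 on the M scale (~0.05 on
beta at mid-methylation), a realistic combined technical + biological
within-group spread for whole-blood arrays. Defaults mirror the study
design this emulates: 235 samples split 119/116 with batch effects off
(they are opt-in so the default cohort is clean); the probe count
defaults to 20,000 as a scaled-down stand-in for an 850k-probe array,
and tests/acceptance use 1–6k probes to keep runs fast at full
statistical fidelity per probe.

Visit histories track a fixed quantile of the reference EDSS-by-age
distribution (mild 0.02–0.18, severe 0.82–0.98) with ≥ 5 years span and
≥ 3 relapse-independent scores by construction, so longitudinal ARMSS
separates groups and eligibility always holds. The ARMSS reference
population is itself synthetic (gamma-distributed EDSS with age-rising
mean, 18–80 years).

What the generator does *not* emulate: probe-level type I/II chemistry
beyond the design-type label, spatial chip artefacts, genotype LD
structure beyond duplicated columns, relapse-window dynamics, treatment
effects on methylation, and realistic inter-CpG correlation (probes are
conditionally independent given cell mixture and planted effects).
Passing recovery tests therefore demonstrates the estimators' internal
correctness and calibration, not their robustness to the correlated
noise of real arrays.

Clock CpGs are linear in planted biological age (slopes ±0.003–0.006
β/year); the severe group's biological age is offset by a configurable
amount (default 1.36 years) so the MAA pipeline has a known effect to
recover. mQTL genotypes are drawn binomially at Hardy–Weinberg
proportions with MAF ~ U(0.2, 0.5).

## Numerical conventions and degenerate inputs

* Beta clipping at 1e-6 everywhere before logits.
* BH-FDR: mergesort (stable) ordering; empty input → empty output.
* Percentiles/IQRs: type-7 throughout (numpy default).
* Reported percentages round to 1 dp (context tallies) or whole
  percent (direction splits), matching conventional reporting.
* Degenerate cases raise with the offending field named (config
  validation, empty classification input, single-sample batches,
  constant regression predictors) or degrade explicitly (constant
  probes p = 1, collinear csDMP designs flagged, zero-SD wMRS DMPs
  dropped with a warning).

## Problem sizes

Tests and the acceptance script simulate 40–235 samples and 50–2500
probes (type-I error calibration uses 2000 null probes at n = 200;
end-to-end recovery uses 1500 probes, 50 planted DMPs at Δβ ≥ 0.05,
n = 200 over five seeds). These sizes were chosen so each statistical
claim is testable at conventional power on a single CPU; per-probe
models are identical at any array size.

## Known limitations

* BMIQ here is a three-beta-state quantile map; it does not implement
  the original's hybrid beta/uniform tail handling, so extreme-tail
  probes can shift slightly differently.
* ComBat is parametric-prior only.
* The elastic net relies on saga; solutions at very small λ on
  separable data converge slowly and non-convergence raises rather
  than silently returning a partial fit.
* The exact HWE test uses the standard conditional enumeration; mid-p
  variants are not offered.
* Deconvolution assumes the reference spans the true cell types;
  reference-free methods are out of scope.
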