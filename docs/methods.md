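# Methods

## The model

The pipeline treats culture-associated DNA-methylation drift as a linear
mean process on the β scale: at a drifting CpG *g*, the expected methylation
fraction of a sample cultured for *d* days is

    E[β_gd] = β_g0 + s_g · d,

with a CpG-specific slope *s_g* (positive for hypermethylating drift) and
unstructured measurement noise around the mean. Drift is *stochastic at the
molecule level*: the per-read methylation states of neighbouring CpGs are
(approximately) independent Bernoulli draws at the per-CpG means, not
coordinated switches of whole alleles. The package's two ends reflect the
two levels: the array-level clock exploits the linear mean trend; the
read-level coherence test checks the independence claim.

Two confounders are modelled explicitly. The CD4⁺/CD8⁺ ratio shifts during
expansion, so any CpG differentially methylated between the two subsets
tracks time through composition rather than drift; those CpGs are removed
against a sorted-cell reference (|Δβ| > 0.10 **or** BH-adjusted p < 0.05,
union rule). Donor age moves a different set of CpGs; candidates whose β
correlates with chronological age (|r| > 0.3) in a large blood reference are
removed after the time screen.

Survival enters through a proportional-hazards model: the log hazard of
death after product infusion is linear in the β values of a subset of drift
CpGs (coefficients reported per 0.1 β, i.e. per 10% DNAm), adjusted for
clinical trial of origin and disease type — the two covariates retained in
the final models; age and sex are not included. The composite
"loss-of-potential" score is a ridge regression of culture time on the
survival-refined CpGs, and its hazard ratio is reported per predicted day.

## Estimators and numerical choices

**Time correlation.** Per-CpG Pearson r against days in culture, each
hybridised sample one observation (donor clustering ignored, matching the
design the screen is meant for). Missing β handled pairwise-complete; < 3
complete pairs → r = NaN with a warning; zero variance → r = 0 by
convention. Selection thresholds are strict inequalities (r > 0.9, not ≥).

**Differential methylation.** Moderated t-test: per-CpG pooled variances
are shrunk toward a scaled-inverse-chi-square prior fitted by method of
moments to the log sample variances (trigamma inversion by Newton
iteration); the prior df d₀ becomes infinite when the observed spread of
log-variances is explainable by sampling alone, in which case the test uses
the common variance with a normal reference. A Welch t fallback is exposed
(`method="welch"`). BH adjustment is applied across all tested CpGs. The
composition filter uses the union rule (|Δ| > δ OR adjusted p < α); the
day-0 vs day-22 contrast uses the conjunction (|Δ| > δ AND adjusted p < α).
A CpG with zero variance in both groups and equal means gets p = 1.

**Penalized clocks.** The objective is
(1/2n)·Σ(yᵢ − b₀ − xᵢᵀb)² + λ[α‖b‖₁ + ((1−α)/2)‖b‖₂²]. Predictors are
standardized internally and coefficients reported on the β scale. The λ
path is log-spaced from λ_max (the smallest λ with an all-zero solution)
down by a factor 0.01 (n < p) or 1e-4 (n ≥ p), 100 points. Cross-validation
folds are stratified by day value (sorted by day, dealt round-robin after a
seeded shuffle within ties) so no fold loses the time gradient; λ is chosen
at the CV-error minimum (`selection="min"`; a one-SE rule is available —
"best-fitted" is read as λ_min). Path solutions use warm-started coordinate
descent at tolerance 1e-4; the final fit at the selected λ is re-solved at
1e-8, and the ridge path (α = 0) uses one eigendecomposition of the Gram
matrix (exact). λ = 0 falls back to least squares. Stationarity is checkable
via `kkt_residual` (subgradient residual on the standardized problem).

**r² convention.** Reported r² is the squared Pearson correlation between
predicted and true days (the scatter-plot convention, insensitive to
additive bias); the coefficient of determination 1 − SS_res/SS_tot is
returned alongside as `r2_cod`. Constant predictions → r² = 0, flagged.
Predictions are not clipped; negative predicted days are reported as-is.

**Cox models.** Fits use the partial likelihood with the Efron tie
correction (the standard default in survival software) and two-sided Wald
p-values; per-CpG screens dummy-code trial and disease with the first level
as reference, drop constant covariate columns with a warning, drop samples
with missing β per CpG, and flag non-convergent fits rather than silently
removing them. Screen selection (HR > 1, p < 0.01) is deliberately
unadjusted for multiple testing — the refinement step is a candidate
generator validated downstream, not an inference — and a BH-adjusted
`q_bh` column is printed alongside for transparency. A Breslow option is
not provided; Efron is the single tie rule.

**Cohort splitting.** Stratified randomization over the cross-classification
of the requested categorical columns, with a numeric `age` column binned
into tertiles. Each stratum contributes proportionally to both cohorts via
largest-remainder apportionment with a seeded lottery on the remainders
(guaranteeing per-stratum counts within ±1 of proportional); strata with
fewer than two patients are merged into the nearest stratum (fewest
differing key components, ties to the largest).

**KM stratification.** Empirical quartile (or median) cuts with ties
assigned to the lower group; empty groups after ties are dropped with a
warning; log-rank test across the remaining groups.

**Deconvolution.** min ‖s − R·f‖₂ s.t. f ≥ 0, Σf = 1, solved by
non-negative least squares on a system augmented with a weighted sum row,
escalating the weight until the constraint holds to 1e-10, then exact
renormalisation. Chosen over unconstrained projection + renormalisation so
the output is always a proportion vector. Up to 10% missing entries are
imputed with reference row means; rank-deficient references are rejected
naming the collinear cell types.

**Read-level coherence.** For each CpG pair, the phi coefficient of the
2×2 read-level table, pairwise-complete over reads (so missing calls at
amplicon ends do not discard whole reads); constant columns contribute
phi = 0. The summary statistic is mean |phi|; its null distribution is
generated by independently permuting each CpG column across reads, which
preserves all per-CpG marginals and destroys only within-read linkage.
p = (1 + #{null ≥ observed}) / (1 + B), B = 1000 by default (add-one rule,
so p is never 0 and minimally 1/(B+1)). Phi was preferred over mutual
information: bounded, signed, closed-form, and directly interpretable as
"switching together".

## The synthetic generator

`SimulationConfig` defaults encode the study conditions the pipeline
targets: 20,000 CpGs; 300 hypermethylating and 3 hypomethylating drift CpGs
with slope 0.01 β/day; 4 timepoints {0, 8, 15, 22} days × 10 donors; 10
age-linked CpGs at 0.001 β/year; 50 composition CpGs with a 0.2 β CD4–CD8
contrast driven by a declining CD4 fraction (0.6 at day 0, −0.015/day);
additive Gaussian β noise with sd 0.02, clipped to [0, 1]. Baselines of
unplanted CpGs are Beta(0.4, 0.4) (bimodal, as methylation arrays are);
planted baselines are drawn uniformly inside a margin that keeps the whole
trajectory in (0, 1), so at the defaults the clipping never distorts the
planted means (clipping bias exists only near 0/1 for noise-driven
excursions of unplanted CpGs).

The clinical simulator gives each patient a trial-specific nominal culture
day (9.5 / 8.5 / 14 days, mirroring typical manufacturing regimens) plus a
patient-intrinsic drift offset δᵢ ~ N(0, 2 days) — the "same nominal time,
different drift" variation the loss-of-potential score is meant to capture.
Survival is exponential with log hazard 0.4 per 10% DNAm at 5 hazard CpGs
(a subset of the hyper-drift set) plus trial and disease effects; the Cox
estimand is invariant to the baseline-hazard shape, so the simplest
constant-hazard generator suffices. Censoring: with probability
`censor_rate` (default 0.3) the observation time is uniform on (0, T_event)
with event = 0 — the requested censoring fraction exactly, by construction.
Hazard uses the *observed* (noise-inclusive) β, so the per-CpG Cox screen
is exactly calibrated against the generator. The CpG universe (baselines,
planted identities) is drawn from `seed` alone, while `cohort_seed`
re-randomizes only the sample/patient draw — replicate cohorts share one
universe, so clocks trained on one transfer to the others. Identical config
(including both seeds) reproduces cohorts bit-for-bit.

What the generator does **not** emulate: array chemistry and detection
failure, batch/platform effects, genotype artifacts, donor-correlated noise
(donors differ only through age and sampling noise), heavy-tailed β noise,
non-linear saturation of drift at late passages, and informative censoring.
Passing recovery tests on these cohorts therefore shows the estimators are
correct and calibrated under the stated model — not that real cohorts meet
the model; on real data the screen's sensitivity depends on how linear the
drift truly is, and the Cox calibration on unmodelled covariates.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` measure: drift-screen
sensitivity/FPR over 20 replicate 20,000-CpG cohorts; clock generalisation
to a held-out 20-sample cohort; optimizer oracles on 50×20 instances;
Cox null calibration pooled over 50 cohorts × 20 CpGs at n = 200, and
CI coverage/HR recovery over 50 replicates at n = 300; end-to-end survival
power over 50 clinical cohorts at n = 200; a 21-point deconvolution mixture
grid; read-level coherence calibration over 200 replicate read sets of
1000 reads (the permutation test's ±0.03 type-I band needs ≥ ~200
replicates for the Monte-Carlo error on the rejection rate, binomial sd
≈ 0.015, to sit well inside the band); and the deterministic 10-CpG filter
fixture plus the 82/32 stratified split of 114 synthetic patients.

## Known limitations

- The moderated-test variance prior assumes a common two-group design per
  CpG; unequal group variances push toward the Welch fallback.
- The elastic-net path at very small λ on highly collinear candidate sets
  converges slowly (coordinate descent); the CV optimum rarely sits there,
  but a forced λ below the path floor should use `fit_at_lambda` directly.
- `split_cohorts` merges undersized strata by a key-distance heuristic; with
  many high-cardinality strata columns the "nearest" stratum is ambiguous.
- Per-CpG Cox fits loop over CpGs (one lifelines fit each); screening
  hundreds of thousands of CpGs is not the intended use — screen after
  drift filtering (hundreds of CpGs).
- The coherence permutation null conditions on per-CpG marginals; it tests
  within-read linkage only, not whether marginals themselves drift.
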