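# Methods

`socioepi` re-implements, as a tested pipeline, the statistical framework of
a longitudinal field study linking early-life social experience in a wild
social carnivore (spotted hyenas) to DNA methylation and to a later-life
stress phenotype measured as fecal glucocorticoid metabolites (fGCMs).
Because the field data are not required to exercise the machinery, the
package ships a synthetic-study generator that emulates the data's
statistical structure with known ground truth; every estimator is validated
by recovery, calibration, and oracle tests against that ground truth.

## The analysis model

The pipeline runs in four parts.

**Part 1 — exposures and stress phenotype.** Each early-life exposure
(maternal-care proportions: close proximity, nursing, grooming; social
network degree, strength, and betweenness in the communal-den (CD) and
den-independent (DI) developmental windows) is standardized to 1 SD and
entered as the fixed effect in a linear mixed model for natural-log fGCM
with a random intercept for animal ID (repeated samples per animal, range
1–18). Adjusted models add sex, human disturbance, age, reproductive state
(four levels) and am/pm sampling time. Effects on the log scale are reported
as percent differences, 100·(exp(β)−1), rounded to the nearest integer.

**Part 2 — exposures and global methylation.** The same exposures are
related to global %CCGG methylation (a LUMA-style genome-average summary) in
mixed models with a maternal-ID random intercept (siblings cluster) and age
as a precision covariate, under four covariate tiers: demographic, social
experience, ecological, and all. Effect modification by maternal rank is
tested with a product term at α = 0.10 (strict inequality). A final model
relates %CCGG to log fGCM.

**Part 3 — mediation.** The classic three-step procedure: (1) exposure →
fGCM; (2) exposure → %CCGG and %CCGG → fGCM; (3) only if every step's
95% bootstrap CI excludes zero, the outcome model is refit adding the
mediator, and mediation is declared when the exposure coefficient shrinks by
more than 10%. Attenuation is computed with the exposure standardized, which
makes the percentage invariant to exposure rescaling; this scale choice is a
design decision (the convention is not forced by the procedure itself).

**Part 4 — site-level EWAS and the meet-in-the-middle screen.** Repeated
log-fGCM measurements are consolidated to one value per animal as the
empirical BLUPs of an intercept-only mixed model (shrunken deviations from
the population mean; in a balanced design the shrinkage factor is
n·σ_b²/(n·σ_b² + σ_e²)). Per-CpG methylated/total read counts are filtered,
modeled site-by-site against the BLUPs with a kinship-aware binomial mixed
model, corrected for test-statistic bias and inflation with an empirical
null, and thresholded with Benjamini–Hochberg FDR at 5%. Differentially
methylated sites (DMSs) are then screened against maternal care and rank
with offset count models; a site "meets in the middle" when its care
association is nominally significant (p < 0.1) **and** of opposite sign to
its fGCM association — the sign pattern expected if better care protects
against a high-stress phenotype.

## Estimation machinery and numerical choices

### Random-intercept LMMs by profiled REML

All Gaussian mixed models have a single random intercept, so the marginal
covariance σ_e²(I + λZZ′), λ = σ_b²/σ_e², is block diagonal and every REML
quantity reduces to per-group sufficient statistics (counts, sums,
cross-products). The REML criterion is profiled to a one-dimensional search
over log λ (bounded scalar minimization, explicit λ → 0 boundary check; a
boundary fit returns variance 0 with a warning). Estimates agree with
statsmodels `MixedLM` to ≤1e−4 (tested), but a fit costs ~1 ms, which is
what makes the bootstrap below affordable. Rank-deficient designs raise an
error naming the collinear columns; missing covariates are handled by
complete-case analysis with logged exclusion counts.

### Percentile cluster bootstrap

Confidence intervals come from a percentile bootstrap with 2000 replicates
by default, resampling *clusters* (the random-intercept unit: animal ID for
fGCM models, maternal ID for %CCGG models) with replacement — the resampling
unit matches the dependence unit the random intercept models. Because the
REML criterion depends on the data only through group statistics, a
replicate is a reweighted sum of precomputed statistics; the λ profile is
minimized for all replicates simultaneously by a vectorized three-stage grid
refinement on log λ (coarse grid, two nested refinements, final resolution
~0.006 on log λ, plus the λ = 0 boundary). Failed refits are skipped and
counted; more than 10% failures aborts with diagnostics. Measured coverage
of the 95% interval in a well-conditioned regime (80 clusters × 3 repeats)
is ~95% (recomputed by `scripts/acceptance.py`).

### Kinship-aware site model (PQL)

For each CpG, methylated counts are binomial with
logit(p) = β₀ + β₁·BLUP + β₂·age + u, u ~ MVN(0, τK), where K is the
additive relationship matrix from the maternal pedigree (diag 1,
mother–offspring 0.5, maternal half-sibs 0.25; sires unobserved and assumed
unrelated). The model is fit by penalized quasi-likelihood: each iteration
solves the working linear mixed model after whitening by the working
weights, with τ profiled by a bounded scalar search over log τ using the
eigendecomposition of W^½KW^½ (scale fixed at 1). This is a deterministic
substitution for the MCMC-based binomial mixed models common in
kinship-aware methylation analysis; its correctness anchor is the exact
reduction to plain logistic regression when K = I and τ → 0 (tested to
1e−4).

When τ hits the zero boundary the site has no usable kinship variance: the
site falls back to a beta-binomial fit without kinship (flagged), or to the
plain binomial GLM when no overdispersion is present either (the
beta-binomial MLE is then itself at its ρ = 0 boundary).

**Small-sample reference.** With ~25 animals, Wald statistics β/SE have
heavier tails than N(0,1); using the normal reference produced spurious FDR
calls under a global null. Wald statistics are therefore referred to a
t(n − p) distribution and mapped back to the normal scale preserving the
p-value (the reported SE is rescaled so β/SE equals the normal-equivalent
z). All downstream machinery operates on z = β/SE as usual, but with
calibrated tails: under the global null the mean number of FDR calls across
20 seeded studies is ~0 (recomputed by the acceptance script).

### Empirical-null correction

Bias and inflation of the site-level z statistics are estimated by fitting a
three-component normal mixture with EM: a central null N(bias, inflation²)
plus one left and one right alternative component. Constraints keep the
decomposition identified: alternative means at least 2 null SDs from the
null mean, alternative SDs at least the null SD, and the null component must
carry the largest weight. Initialization is at robust method-of-moments
values (median, MAD) with 10 seeded random restarts; the best-likelihood
valid solution wins, so the estimate is deterministic given the seed. This
deterministic EM replaces the Gibbs-sampler implementations common in this
niche, whose hyperpriors are tool-specific; only the bias/inflation
contract is preserved. Corrected
quantities are z′ = (z − bias)/inflation, β′ = β − bias·SE,
SE′ = SE·inflation (so β′/SE′ = z′), and p′ the two-sided normal tail of z′.
Planted bias 0.3 / inflation 1.2 on 10⁴ null scores is recovered within
±0.05, and corrected null p-values are uniform (KS < 0.02 at 5000 scores).

### CpG filtering

Order is fixed: (1) coverage — a site is kept only if **every** analyzed
individual has ≥10 reads (the conventional 10× floor; requiring it
per-sample avoids missing-cell handling in the site model); (2) mean
methylated fraction within (0.10, 0.90); (3) drop the 5% of survivors with
the lowest inter-individual variance of methylated fractions (variance of
fractions is our operationalization of "inter-individual variation", which
the source analysis does not define; ties broken by site order;
floor(0.05·m) sites dropped, so the variance stage is a fixed fraction of
its input and is deliberately not re-applied downstream). Counts removed at
each stage are logged. Coordinates are 0-based half-open internally;
Bismark-coverage files (1-based inclusive) are converted on read.

### Count models for the screen

Care/rank associations at DMSs use GLMs with methylated reads as outcome and
log(total reads) as offset. A Poisson fit is tested for overdispersion
(Pearson χ² against the upper 5% χ² tail, strict exceedance); when
triggered, a negative binomial model is used instead. Sign comparison uses
the raw care-model slopes against the inflation-corrected fGCM-model slopes,
since the two model families are separate.

### Networks

Association networks use the simple ratio index x/(x + y_a + y_b) (the
default in the association-index literature); pairs never seen together
carry no edge. Degree is the unweighted count of associates, strength the
sum of incident weights, and betweenness the normalized weighted betweenness
with edge distance 1/weight (stronger association = shorter path), ties
among equal-length paths split evenly. On all graphs with ≤6 nodes these
equal exhaustive path enumeration (tested on 210 random graphs). The DI
window starts the day after the CD window ends and is duration-matched to it
exactly (day resolution, both endpoints included).

## The synthetic-study generator

The generator emulates the study's statistical skeleton, not its biology:

- **Pedigree/kinship**: founder mothers with 2 cubs each (80 focal animals
  by default, matching the behavioral-analysis sample; the genome-wide
  module uses 25, matching the sequenced subsample); additive relationship
  by the tabular method.
- **Behavior**: per-pair focal surveys with per-minute care indicators
  (nursing and grooming minutes are subsets of close-proximity minutes, as
  both occur within 1 m); ~500 co-occurrence sessions with am/pm labels
  spanning every cub's CD and DI windows; attendance driven by a latent
  gregariousness so that planted sociability is recoverable from realized
  co-occurrence. Human disturbance lowers care (configurable sign/size);
  CD window length ~ N(6.98, 1.74²) months, the study's observed
  distribution.
- **fGCM**: log-normal with individual random intercept (SD 0.35), residual
  SD 0.5, 1–18 repeats per animal; planted per-SD slopes default to the
  study's adjusted estimates (network −0.12, care 0).
- **%CCGG**: Gaussian around 75% with maternal random intercept (SD 1.0)
  and a planted care slope of 1.36 per SD (the study's headline estimate).
- **Methylation counts**: per-site logit-scale model with
  kinship-correlated random effects (τ = 0.5), site intercepts ~ N(0,1)
  (most sites inside the 10–90% mean band), coverage 1 + Poisson(29), and a
  configurable fraction of truly associated sites with logit effect 1.0.
- Effects are planted on the *realized*, standardized exposures computed
  from the generated records by the same code the analysis uses, so
  recovery tests have exact targets; every dataset ships a ground-truth
  ledger (planted slopes, random-effect draws, true-DMS set).

What the generator does **not** emulate: overdispersed/zero-inflated
coverage beyond the shifted Poisson (the coverage filter removes the
affected cells anyway), fine within-day observation structure (only an
am/pm label), spatial den structure, cell-type heterogeneity in blood, and
any sequence-level realism. Passing tests therefore demonstrate that the
estimators recover what they claim under the modeled dependence structure
(repeated measures, maternal clustering, pedigree correlation) — not that
the field study's substantive estimates are correct.

## Problem sizes used by tests and the acceptance script

Simulation studies run at sizes chosen to make their Monte-Carlo error small
relative to the asserted bands: bootstrap coverage over 200–300 datasets at
500 replicates each; EWAS null calibration over 10–20 seeded studies of
2000 sites × 25 animals; the planted-effect regime at 1000 sites with 50
true sites; mediation behavior over 60–100 chains of 60 individuals × 3
repeats at 300 bootstrap replicates.

## Known limitations

- Only a single random intercept is supported (no random slopes, no crossed
  random effects); this matches every model in the analysis design.
- PQL is approximate for binomial mixed models at low coverage; the
  empirical-null correction absorbs the resulting scale miscalibration but
  not site-specific bias.
- The beta-binomial fallback estimates its Hessian numerically; pathological
  sites degrade to quasi-binomial SE scaling with a non-converged flag.
- The meet-in-the-middle screen treats the fGCM-model sign as fixed when
  classifying hits; joint uncertainty in the two signs is not propagated.
- Loading externally supplied (non-simulated) study directories end-to-end
  through the CLI is not wired; the module functions accept user tables
  directly.
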