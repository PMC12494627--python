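# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `sweetwin`, in enough detail that a maintainer can
predict what the code will do without reading it.

## The classical twin model

Phenotypic variance is partitioned into additive genetic (A), shared
environmental (C), nonadditive/dominance genetic (D) and unique
environmental (E) components.  The design assumptions are the standard ones:
MZ twins share all segregating genetic variation, DZ twins half of the
additive and a quarter of the dominance variation on average; environments
relevant to the trait are equally similar for MZ and DZ pairs; genetic and
environmental influences are independent and additive (no gene–environment
correlation or interaction, no sex limitation, no epistasis beyond D).
Because all pairs are reared together, C and D are not jointly identified:
the model families are ACE and ADE plus their AE, CE, DE and E submodels,
with E always present (it absorbs measurement error).

**Direct symmetric parameterization.**  Variance components enter the
likelihood as free real parameters — no Cholesky factors, no non-negativity
constraints.  A truly-zero component then sits in the interior of the
parameter space, so its estimate is unbiased around zero (it may go
negative) and the LRT for dropping it is calibrated χ² with df equal to the
number of dropped parameters.  The only hard requirement is that every
implied pair covariance matrix stays positive definite; parameter proposals
violating it receive a large finite penalty that slopes back toward the
feasible region, which keeps quasi-Newton line searches stable.

**Likelihood.**  Full-information ML: complete pairs contribute bivariate
normal densities with the expected pair covariance; twins whose co-twin is
unphenotyped contribute the univariate marginal.  Nothing is imputed and
singletons are never dropped.  Means are linear in covariates (age centered
at the sample mean, in years; sex coded F=0/M=1), with slopes shared across
twin order and zygosity.  Opposite-sex DZ pairs are pooled with same-sex DZ
pairs (genetic correlation 0.5); sex enters only the mean model.

**Saturated model and assumption tests.**  The saturated baseline estimates
two means, two variances and one covariance per zygosity group (10 free
parameters for two groups, plus shared covariate slopes).  Assumptions are
tested by a sequential chain of restrictions — means equal across twin
order, then variances across order, then means across zygosity, then
variances across zygosity — each step compared to the previous model by
LRT (df 2, 2, 1, 1).  The sequential layout keeps every step's test at its
nominal level; an alternative is to compare each restriction to the full
saturated model with cumulative df, which the chain subsumes.

**Ordinal (liability-threshold) model.**  The three status categories
(SD < MSL < ESL) are treated as cuts of a latent standard-normal liking
liability: mean 0, variance 1, standardized components summing to one
(E = 1 − A − C − D, so the AE model has a single free component), and two
free thresholds interpretable as z-scores, shared across zygosity within a
fit.  Covariates shift the liability mean; thresholds absorb the intercept.
Pair likelihood cells are bivariate-normal rectangle masses; with no
covariates the data collapse to two 3×3 contingency tables plus singleton
category counts, which makes each likelihood evaluation O(1).

**Bivariate AE model.**  Per pair, the four observations (two twins × two
traits) are 4-variate normal.  Within-person cross-trait covariance is
A₁₂ + E₁₂; cross-twin cross-trait covariance is A₁₂ (MZ) or A₁₂/2 (DZ).
All six components are free.  Rows with missing slots contribute the
marginal normal of their observed entries (rows are grouped by missingness
pattern so each pattern costs one solve).  Only the AE structure is
implemented for two traits: the univariate analyses this package mirrors
retained AE everywhere, and C/D cross-paths would not be identified any
better.  The decomposition rP = rg·√(h²₁h²₂) + re·√(e²₁e²₂) holds exactly
for the standardized solution and is verified to 1e−8 in the tests.

## Numerical choices

* **Bivariate normal CDF** via Owen's T function
  (`scipy.special.owens_t`): Φ₂(h,k,ρ) = (Φ(h)+Φ(k))/2 − T(h,a_h) −
  T(k,a_k) − β.  Exact zeros in h or k are nudged by 1e−13 (Φ₂ is
  continuous there); |ρ| ≥ 1−1e−12 falls back to the Fréchet bounds.
  Accuracy is ~1e−14, far inside the 1e−8 contract; the unit tests
  cross-check against `scipy.stats.multivariate_normal.cdf` and the
  arcsine closed form for quadrants.
* **Optimization**: L-BFGS-B on scale-free coordinates (each parameter
  divided by a moment-based scale — √variance for means, variance for
  components, 1 for thresholds), numeric gradients with step 1e−8, ftol
  1e−13.  Multi-start: Falconer/moment starts (e.g. a² = 2(r_MZ − r_DZ)),
  an E-only start, and an equal-split start; infeasible starts are
  discarded.  A Nelder-Mead rescue runs only if every start is trapped in
  the penalty region.  `converged` requires the scaled gradient norm
  relative to |loglik| to be small and the objective to be finite.
* **Polychoric correlation**: two-step estimator — thresholds from the
  double-entered margins, then a bounded 1-D likelihood maximization for ρ
  on [−0.999, 0.999]; SE from a central second difference at the optimum.
  Estimates at the clip are flagged `boundary` and reported without SE.
  Two-step is used instead of joint ML for speed and stability; at the
  table sizes involved the difference is far below the SE.
* **Profile-likelihood CIs**: the bound solves 2(ℓ̂ − ℓ_profile(v)) = χ²₁
  at the level; constrained refits use SLSQP with an equality constraint on
  the profiled quantity (raw parameter, h², e², or total variance),
  warm-started along the bisection path; bracketing doubles outward from
  the estimate and bisection stops at 1e−4 of the parameter scale.  If no
  bracket is found within 40 doublings the interval is flagged open-ended.
  On a quadratic likelihood this reproduces the Wald interval to 1e−4
  (tested).
* **LRTs** use naive χ² df — exactly what the direct symmetric
  parameterization licenses (no boundary mixture corrections).
* **Degenerate inputs**: empty status categories raise (threshold at
  infinity); zero-variance traits raise for correlations; a bivariate fit
  whose data imply a singular 4×4 covariance (e.g. duplicated traits) is
  returned with a `boundary` flag rather than trusted point estimates.

## Sweet-liking status classification

Raw liking ratings of the sucrose solution on the 120-mm Labeled Affective
Magnitude scale are rescaled linearly to −50..+50
(score = rating·100/120 − 50) and cut at configurable cut-offs defaulting
to (0, 15): scores below 0 are sweet-dislikers, above 15 extreme
sweet-likers, and the closed interval [0, 15] moderate sweet-likers.
Boundary scores are assigned to MSL because the defining rule quotes strict
inequalities only for the outer groups; the cut-offs derive from a
sensitivity/specificity analysis for a 0.5 M solution and are applied to
0.58 M data as the nearest calibrated concentration — both facts are why
they are config values, not constants.  Category order SD < MSL < ESL is
fixed globally (reversing it only flips threshold signs).

The published summary tables are not mutually consistent about the raw
rating scale: the demographic table's liking mean/SD cannot reproduce the
printed status proportions through the rescale-and-cut-off chain.  The
pipeline therefore supports two classification modes: `cutoffs` (the
default for real LAM data) and `quantile`, which z-scores the trait and
cuts at liability thresholds implied by target status proportions.  Preset
runs use `quantile` mode so that simulated cohorts reproduce the printed
proportions while keeping the printed trait variance.

## The synthetic-data generator

`simulate_cohort` draws, per pair, Gaussian component deviates with the
design's cross-twin correlations and sums them with the linear mean model;
twins share age (drawn per pair) and, for same-sex classes, sex.
Opposite-sex DZ pairs get discordant sexes by construction.  Incomplete
pairs are created by masking one twin's phenotypes at a per-zygosity rate.
Deviates are Gaussian — the likelihood's own assumption — so recovery tests
certify the estimators *under the model*; they say nothing about skewed or
heaped real rating data, scale-use differences between twins, or
non-random missingness.

The presets encode the two cohorts' published study conditions as defaults
and are not tuned elsewhere:

* `uk_like`: 244 MZ + 250 same-sex DZ pairs (no opposite-sex pairs), liking
  variance 384.6 with h² = 0.48, mean 52.62; ages 55.64 ± 12.51; 90%
  female; incomplete-pair rates 7%/4%; status proportions 42/22/36
  (SD/MSL/ESL); a second food-liking trait with h² = 0.52 and rg = 0.31,
  re = 0.06 to liking.
* `fin_like`: 111 MZ + 80 same-sex DZ + 68 opposite-sex DZ pairs, variance
  218.5 with h² = 0.30, mean 60.29; ages 22.67 ± 0.47; 60% female;
  incomplete rates 12%/15%/37%; status proportions 24/32/44; secondary
  trait h² = 0.53 with rg = 0.19, re = 0.22.

Where a published value did not exist (the secondary traits' means and
total variances, which are reported only standardized), unit variance and a
mid-scale mean were chosen once as generic hedonic-scale values.
`beta_age` and `beta_sex` default to 0; the printed tables do not report
covariate slopes.

## Model selection and heterogeneity testing

Model search is backward elimination along the nested chain the families
define.  ACE and ADE attain the same maximized likelihood under direct
symmetric parameterization (both interpolate the same three second-moment
statistics), so the family label is taken from the sign of the
unconstrained C estimate (negative C — DZ correlation below half the MZ
correlation — is the ADE pattern).  The non-additive component (C or D) is
tested first: a non-significant LRT at α = 0.05 drops it, landing on AE;
A is tested only from the reduced model (AE vs E), and dropping A from the
full (→ CE/DE) is attempted only when C/D must be retained.  Testing A
last is deliberate: D can mimic A almost perfectly at twin-study sample
sizes, so a "drop the least significant of all components" rule would
frequently discard A in favour of a dominance-only model that the chain
structure of the hypotheses does not support.  Under an AE truth the
selection event reduces to a single calibrated χ²₁ test, giving AE in ≈95%
of replicates at the preset sample sizes.

Heterogeneity across cohorts or sexes uses multi-group fits: the omnibus
test ties all parameters across groups (df = (G−1)·P) against the fully
free fit; per-parameter follow-ups tie one parameter at a time (df = G−1)
and, in the pipeline, run only when the omnibus rejects.  Sex-stratified
fits use same-sex pairs only, since an opposite-sex pair belongs to no
single sex stratum.  For ordinal fits the parameter set includes both
thresholds, so cohort differences in category prevalences are attributable
to a specific threshold.

## Problem sizes

Simulation-backed checks use the published pair counts (244+250 and
111+148) with 200 replicates for the headline heritability means, 1000
replicates for LRT calibration, and 5000+5000 pairs for bias checks —
sizes at which Monte-Carlo error (≈0.003–0.008 on a mean h²) is an order
of magnitude below the comparison tolerances.

## Known limitations

* No sex-limitation models (qualitative or quantitative) and no
  gene–environment interaction — excluded by the design assumptions above.
* Ordinal-by-continuous bivariate models are not implemented (the liability
  machinery would permit them); neither are ≥3-trait models.
* The ordinal model assumes thresholds shared across zygosity within a fit
  and covariates acting on the liability mean only.
* Polychoric SEs come from the profile curvature in ρ with thresholds held
  fixed (two-step), which slightly understates uncertainty relative to
  joint ML.
* Whether singletons entered the original ordinal analyses, and whether
  thresholds varied by sex within cohort, is not documented; here
  singletons always contribute marginals and thresholds are sex-invariant,
  both switchable at the API level.
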