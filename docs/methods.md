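# Methods

## The problem

Longitudinal neuropsychological batteries produce many correlated outcome
measures per person per visit.  Fitting each outcome separately against an
exposure (here: a remote mild traumatic brain injury with loss of
consciousness, in a healthy ageing cohort) wastes the information the
outcomes share and inflates sign and magnitude errors.  `nestpool`
implements the nested-domain alternative: outcome-level effects are
partially pooled toward the mean of the cognitive domain they were
assigned to *a priori*, and domain-level means are pooled toward one
overarching effect.

## Model

Let outcome *k* belong to domain *d(k)*; observations are indexed by
subject *i*, outcome *k* and time *t* (in wave units, one unit = 18
months, 0 at baseline).  All outcomes are oriented so larger = better and
standardized to mean 0 / SD 1 pooled over groups and waves, so every
coefficient below reads like a partial correlation coefficient.

Mean structure (group-by-time variant):

    y_ikt = beta_int[g(i), k] + beta_slope[g(i), k] * t
            + u_i + v_{i,d(k)} + (w_i + z_{i,d(k)}) * t + eps_kt

with group g in {control, exposed}.  Every effect family (e.g. the exposed
intercepts over the 22 outcomes) is composed as

    beta_k = mu + delta_domain[d(k)] + delta_outcome[k].

The chronic group contrast and the time-by-group interaction contrast are
*derived* quantities, computed draw-wise as exposed minus control — not
free parameters — because both groups' intercepts and slopes are reported
alongside their contrast.

The within-exposed variant replaces the group families by six nested
families: standardized log10 LOC duration, standardized age at first
injury, time, and the covariates age at baseline, WTAR IQ and sex (0/1).
Covariates receive the same three-level nesting as the exposures; whether
the original analysis nested them is unknowable from the published
description, so this is a documented modelling choice (they are nuisance
terms either way).  No free intercept family is included: outcomes are
standardized to mean ~0 and the subject-level random intercepts absorb
residual offsets.

The domain-agnostic exploratory variant removes the hierarchy entirely:
per-outcome effects are independent with diffuse N(0, 1000^2) priors, and
the person-by-domain random effects are dropped (measures are not grouped
into domains), while person-level intercepts and slopes are retained so
longitudinal dependence survives.  In the exposure version the covariate
families are dropped as well.

### Priors

| block | prior |
|---|---|
| overarching means mu | Normal(0, 100^2) |
| domain / outcome deviations | Normal(0, tau^2), tau ~ Half-Cauchy(1) |
| random-effect SDs sigma_u, sigma_w, sigma_v, sigma_z | Uniform(0, 10) |
| residual scale sigma_k (per outcome) | Uniform(0, 10) |
| residual df nu_k | nu = 1/eta, eta ~ Uniform(0.001, 0.5) (so nu in (2, 1000)) |
| agnostic per-outcome effects | Normal(0, 1000^2) |

Residuals are Student-t per outcome: a small nu_k fattens the tails and
down-weights gross outliers; nu_k near its upper bound recovers a normal
residual.  The half-Cauchy is the positive half of a Cauchy(0, 1).

## Sampler

The engine is a blocked Gibbs sampler, numba-compiled, equivalent in
target to a BUGS/JAGS-style Gibbs fit of the same graph:

* the t likelihood is represented as a scale mixture of normals (latent
  precision multiplier lambda_n ~ Gamma(nu/2, nu/2) per observed cell),
  making every location block conditionally Gaussian with closed-form
  updates (overarching means, deviations, all random effects);
* half-Cauchy hierarchy SDs use the inverse-gamma auxiliary-variable
  representation, so they are conjugate as well;
* bounded SDs (uniform priors) and eta = 1/nu are updated by univariate
  slice sampling — exact and tuning-free;
* the *centered* parameterization is used: with fully conjugate updates it
  mixes well and keeps the kernel simple.  Non-centering is a remedy for
  funnel geometry under gradient or generic-Metropolis samplers, which do
  not arise here.

Draws are bit-reproducible for a fixed seed (per-chain seeds are spawned
from the master seed).  Individual random effects are updated but not
stored; the retained draws cover all effect-family parameters, hierarchy
SDs, random-effect SDs, residual scales and dfs.

Defaults mirror the original protocol: 50,000 kept samples thinned every
5th step.  The protocol does not state its chain count or burn-in;
defaults are 4 chains (PSRF needs at least 2) and 5,000 warm-up iterations
per chain, documented here rather than asserted as the original settings.
Desk-scale work (tests, examples) uses 4 chains x 2,000 kept with 500
warm-up iterations, which the convergence gate deliberately fails — the
gate (PSRF < 1.1 and ESS > 1000 on every reported quantity) is calibrated
to the full budget.  1.1 is a documented cut-off; the source protocol
states monitoring, not a threshold.

## Diagnostics and reporting

* **PSRF**: the classic two-sided Gelman-Rubin statistic,
  sqrt(Vhat+/W) with Vhat+ = (n-1)/n W + B/n — no rank normalization, no
  chain splitting, matching the 1992 form (hand-checkable: identical
  chains give sqrt(0.75), unit-shifted chains give sqrt(1.05)).
* **ESS**: initial-positive-sequence autocorrelation summation (Geyer
  pairs, forced monotone), autocovariances pooled across chains, capped at
  the total draw count.  Constant chains report ESS = 0 with a warning.
* **HDI**: sorted shortest-window estimator — the narrowest interval of
  ceil(mass * n) consecutive sorted draws.  Assumes unimodality;
  multimodal posteriors are not handled (and do not arise for these
  Gaussian-mean-structure quantities).  80% intervals nest inside 95% ones
  by construction.
* Summaries report posterior means with 80% and 95% HDIs per outcome and
  per domain, in fixed D1..D7 order, on the standardized scale; raw-unit
  back-transformation is available through the stored scaling record.

## Preprocessing conventions

* Orientation before scaling; scaling uses the sample SD (ddof = 1, as R's
  `scale()`), computed over sorted values so results are exactly invariant
  to row order.
* Time is coded in wave units (0, 1, 2).  The published description never
  states whether time itself was standardized ("numeric variables were
  scaled" is ambiguous); wave-unit coding keeps slopes interpretable as
  change per 18 months and is flagged as a reporting-scale caveat.
* LOC duration enters as log10(minutes); exposure features are
  standardized within the exposed group.
* Missing outcome cells are simply dropped from the likelihood
  (observed-data analysis); no imputation.
* Matched-control selection is greedy in case order: exact on sex, APOE
  allele count and education band; nearest-neighbour Euclidean distance on
  standardized age and WTAR; without replacement; seeded tie-breaking.
  Cases short of eligible controls keep what exists and are logged.
  Optimal (global) matching is a non-goal.

## Synthetic cohort generator

The generator is the model run forwards, with marginals calibrated to the
cohort composition it stands in for:

* 53 exposed / 104 control subjects; waves at 0/18/36 months; wave-1
  retention 1.0 and wave-2 retention 89/104 (control) and 52/53 (exposed),
  matching the sessions tabulation — so missingness is monotone;
* age ~ N(70.2, 5.7^2), WTAR IQ ~ N(110.2, 6.5^2), ~41% female, education
  bands (7-12 / 13-15 / 15+) at (0.37, 0.14, 0.49), APOE e4 counts at
  (0.67, 0.29, 0.04);
* log10 LOC minutes from a two-component normal mixture (0.8 weight on
  N(0.83, 0.55) minutes-scale bump, 0.2 on N(2.9, 0.8) long tail),
  truncated to [log10 0.03, log10 30240] and calibrated to median ~10 min;
  the exact tail shape is unconstrained by any published statistic and is
  synthetic;
* age at first injury lognormal around median 18 years, truncated to
  [4, 67];
* random-effect SDs (0.5, 0.12, 0.3, 0.08) and residual scale 0.703 at
  nu = 8 chosen so the latent standardized outcome has total variance ~1
  at baseline — recorded true effects therefore live on (approximately)
  the scale the analysis reports.  The person-by-domain intercept SD 0.3
  makes within-domain outcome correlations exceed between-domain ones,
  the structure the nested model exploits.

What the generator does **not** emulate: per-measure missingness patterns
(only whole-visit attrition), covariate drift over waves (covariates are
time-constant), practice effects, floor/ceiling effects of real
instruments, and any dependence between matching variables and outcomes.
Passing recovery/calibration tests on these cohorts therefore shows the
estimator is correct *for data satisfying the model's assumptions*; it
cannot show robustness to real-world violations beyond the ones modelled
(heavy tails, attrition).

Scenario presets plant effects at the magnitudes the analysis reports:
`paper_scale` (intercept contrasts 0.17-0.24 on the five largest-effect
outcomes, slope contrasts 0.08-0.11), `strong` (0.5 / 0.2), `severity`
(LOC effects -0.26 / -0.29 on the logical-memory outcomes), `heavy_tails`
(nu = 3 on two outcomes), `null` (all zero).

## Numerical choices and degenerate inputs

* Slice samplers shrink from the full bounded support; 200-iteration
  safety cap (returns the current value if ever hit — practically
  unreachable).
* A one-domain / one-outcome map is accepted: the composition collapses to
  mu plus two weakly identified deviations; reported composed effects
  remain identified.
* Single-wave designs are rejected (slopes unidentifiable); single-group
  designs are rejected for the group model; any control subject is
  rejected by the exposure model; constant outcome or exposure columns
  raise zero-variance errors naming the column.
* Figure-level N discrepancies in the emulated study (102/52 vs 104/53)
  are treated as analysis-time exclusions: the pipeline analyses whatever
  survives validation.

## Problem sizes used by the test and acceptance suites

Correctness is established on synthetic data against independent oracles:
closed-form conjugate posteriors, hand-computed PSRF values, quantile-grid
HDIs, AR(1) ESS theory, and the generator's recorded ground truth
(coverage, calibration, shrinkage, robustness).  Replicate studies use the
default cohort sizes with the reduced sampler budget (4 x 2,000 kept, 500
warm-up) and 10-20 replicates — enough for the 10-percentage-point
tolerances on coverage checks, and the package's chosen desk-scale
configuration.  The paper-budget protocol (50,000 kept, thin 5) is
exercised end-to-end on a reduced battery (4 outcomes / 2 domains, 30
subjects) where it clears the ESS > 1000 gate.

## Known limitations

* The HDI estimator assumes unimodal marginal posteriors.
* The Gibbs sampler's worst-mixing directions are the overarching-mean vs
  deviation trade-offs; composed effects (the reporting surface) mix much
  faster than their components.  ESS on components can look alarming while
  contrasts are fine; the gate is therefore evaluated on reported
  quantities.
* Education bands are used for matching only, never as a model covariate;
  APOE likewise.
* No model comparison (WAIC/LOO), no spatial/temporal residual
  correlation, no multiple imputation, no propensity-score matching.
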