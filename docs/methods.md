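# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of `tempdisc`.

## Hierarchical choice model

One observation is a binary choice between a smaller-immediate amount
`A_ss` (delay 0) and a larger-later amount `A_ll` at delay `D` days.
Subjective values come from a discount family:

- hyperbolic: `V = A / (1 + kD)` (primary family),
- exponential: `V = A e^(-kD)`,
- quasi-hyperbolic (beta-delta): `V = A` at `D = 0`, else `A β δ^D`.
  In the hierarchical fit δ is parameterized as `exp(-k)` so that all
  families share the condition-specific `ln k` structure, and β (applied
  only to delayed outcomes) is a participant-level parameter on the logit
  scale with a hierarchical normal prior centered at logit⁻¹(1.5) ≈ 0.82.

The choice rule is the field-standard softmax in the value difference,
`P(LL) = logistic(τ (V_LL − V_SS))`, with a participant-level inverse
temperature τ (units: 1/$) shared across conditions. τ trades off against
the dollar scale of the items; it is identified because amounts are fixed
by design.

Participant `ln k` vectors across the condition levels (frames `delay`,
`date`, or magnitude bands `small`, `medium`, `large`) are multivariate
normal with group means `μ_lnk[c]` (prior `Normal(-4, 3)`, weakly
informative around typical monetary-choice rates of ~0.02/day), SDs
`Half-Normal(2)`, and a correlation matrix with an LKJ(2)-type prior placed
on canonical partial correlations (exact LKJ for two conditions).
`ln τ_i ~ Normal(μ_τ, σ_τ)` with `μ_τ ~ N(0,1)`, `σ_τ ~ Half-Normal(1)`.
The correlated-condition structure respects the within-person pairing that
the downstream paired tests rely on. The magnitude model pools both frames'
choices into the three bands (18 observations per band and participant).

### Sampler

Estimation is by adaptive Metropolis-within-Gibbs, vectorized across chains
and participants:

- participant blocks `(ln k[i,·], ln τ_i[, logit β_i])` use random-walk
  Metropolis with per-participant step sizes adapted during warmup toward
  30% acceptance (two sweeps per scan), followed by an independence
  "prior-refresh" move that proposes `ln k[i,·]` from the conditional prior
  `N(μ, Σ)` (the prior cancels, so acceptance is the pure likelihood
  ratio) — this keeps weakly identified participants, e.g. all-larger-later
  responders, decorrelated;
- group means are exact conjugate Gibbs draws given the participant values;
- the group covariance is updated by independence Metropolis-Hastings from
  the inverse-Wishart conditional likelihood of the participant deviations
  (df = n − C − 1, scale = Σᵢ devᵢdevᵢᵀ), with the acceptance ratio
  correcting for the half-normal/LKJ prior; the (log σ, atanh
  partial-correlation) parameterization's Jacobian is evaluated by central
  differences (C ≤ 3). Two adaptive random-walk sweeps remain as a
  fallback. Without the independence step, the σ_lnk conditional mixes an
  order of magnitude more slowly at cohort sizes in the hundreds;
- joint deviation/SD scale moves (all conditions together, then each
  condition) and joint translation/scale moves for the τ hierarchy break
  the random-walk stickiness between hierarchy levels that a centered
  parameterization otherwise suffers; their step sizes shrink as 1/√n and
  adapt during warmup.

Defaults are 4 chains × (1000 warmup + 1000 draws); the recovery tests use
2 × (500 + 400), which reaches split-R̂ ≲ 1.03 on group-level parameters for
cohorts of 40–200 participants. Diagnostics (split-R̂, ESS via ArviZ,
acceptance rates) are attached to every fit; a fit is flagged non-converged
(not silently accepted) when max R̂ > 1.05. Random-walk MH has no
divergences; the `divergences` field is kept at 0 for interface uniformity.

Point estimates are posterior means. The date/delay effect (DDE) is
`ln k(delay) − ln k(date)` of the point estimates, the magnitude effect
(ME) `ln k(small) − ln k(large)`.

## Predictive accuracy

The pointwise log-likelihood matrix (draws × observations) is recomputed
from the stored participant draws. PSIS-LOO uses the standard
Pareto-smoothed importance-sampling recipe (smoothing via `arviz.psislw`);
observations with tail index k > 0.7 are flagged, not refit. `elpd` is the
sum of pointwise contributions, its SE `sqrt(N · var)` with sample variance;
two models are "distinguishable" exactly when `|elpd_diff| ≥ 2·SE_diff`,
with `SE_diff` from the paired pointwise differences. The pointwise unit is
the observation by default; a `groups` argument aggregates to
leave-one-participant-out. Per-participant WAIC is
`−2 Σ_j (lppd_j − p_waic,j)` over the participant's observations (variance
penalty with denominator S−1), so participant WAICs sum to the dataset
WAIC.

## Framing-effect inference

- **BEST** (one-group): t likelihood with location μ, scale σ, normality ν;
  priors `μ ~ Normal(mean(d), 1000·SD(d))`, `σ ~ Uniform(SD/1000, SD·1000)`,
  `ν ~ 1 + Exponential(29)`. Fit by adaptive MH (3 chains; 30,000 retained
  draws by default). Reported: P(μ > 0), posterior median of μ ("median
  paired difference"), 95% HDI. It operates on point-estimate differences;
  this is an interpretation choice, documented here.
- **Paired t** with Hedges `g_av = J · mean(d) / ((SD_x + SD_y)/2)`,
  `J = 1 − 3/(4·df − 1)`; CI by noncentral-t inversion of the observed t.
- **Repeated-measures ANOVA** (via pingouin): Greenhouse-Geisser ε applied
  to the dfs, partial η², Mauchly's test, all-pairs post-hoc paired t-tests
  (uncorrected by default, Holm optional). A matrix with no within-subject
  condition variation returns F = 0 by convention.

## Factor pipeline

- **Heterogeneous correlations:** Pearson (continuous-continuous),
  polyserial (mixed), polychoric (ordinal-ordinal), all two-step ML:
  thresholds from marginal normal quantiles, then ρ by bounded
  maximization of the cell-probability likelihood, capped at ±(1−10⁻⁶).
  The bivariate normal CDF is a vectorized Gauss-Legendre implementation
  (Genz/Drezner-Wesolowsky), accurate to ~1e-14 (verified against scipy).
  Pairs use pairwise-complete observations. Non-PSD matrices are smoothed
  by eigenvalue clipping at 1e-6 and rescaling to unit diagonal, with a
  flag recorded.
- **Factor count:** CNG scree test — for each admissible split t, the
  difference between the slope of the eigenvalue triplet after t and the
  triplet ending at t; maximal slope increase wins, ties to the smallest t.
  The minimum returnable count is 3 (the test needs two 3-point segments).
- **Extraction:** ML profile objective over uniquenesses (eigenvalue form),
  analytic gradient, L-BFGS-B with bounds [0.005, 1] and an SMC-based
  start; loadings from the scaled eigenvectors.
- **Rotation:** oblimin with γ = 0 (direct quartimin) by the oblique
  gradient-projection algorithm, identity plus 9 random orthonormal starts,
  lowest criterion kept. Columns ordered by explained variance; signs set
  so salient loadings (|λ| > 0.3) are predominantly positive.
- **Scores:** Thurstone regression weights `W = R⁻¹ (Λ Φ)` on standardized
  items, standardized to mean 0 / SD 1. Participants with missing items are
  scored on available items with the weight mass rescaled (warning logged).
- **Bootstrap CIs:** case resampling; each replicate refit end to end;
  replicate factors aligned to the full-sample solution by Tucker-congruence
  assignment plus sign flips (guards against label switching); percentile
  2.5/97.5 intervals; replicates that fail to converge are dropped, >10%
  dropped is an error. Default 1000 replicates.

## Association layer

Per-variable outlier masks exclude values more than 3 SD from the mean
(moments from the full non-missing sample, computed once). Correlations use
pairwise mask intersections; regressions listwise intersections. The Holm
family is the two framing versions per predictor; single-DV analyses (DDE,
ME, WAIC) are reported uncorrected. OLS standardizes the outcome and all
non-binary regressors (so coefficients are standardized βs — the outcome
standardization is a documented choice), uses HC3 sandwich SEs by default
(HC0–HC3 selectable), rejects rank-deficient designs naming the collinear
columns, and attaches the studentized (Koenker) Breusch-Pagan test
(statistic n·R² of the squared-residual regression; defined as 0 for
constant squared residuals). Gender enters as two dummies (male, diverse;
female reference); unrepresented categories are dropped.

The a priori power computation uses the exact density of the sample
correlation under bivariate normality (hypergeometric form, evaluated in
log space) integrated beyond the exact null critical value, with bisection
over n — not the Fisher-z approximation. It reproduces the classic target
of n = 782 for r = 0.10, α = 0.05 two-tailed, power 0.80.

## Synthetic cohort: what it emulates, and what it does not

The generator's defaults are the emulated study conditions: 800 recruited
participants with an 8.5% attention-check failure rate; group mean ln k
−4.8 (SD 1.8) in the delay frame; a within-person frame effect of 0.43
(person-level SD 0.6) entering only through ln k; near-zero-mean
magnitude-band offsets (0.53, −0.09, −0.44) scaled so small − large = 0.98,
declining monotonically with reward size, with a person-level SD of 0.6 on
the small−large gap; `ln τ ~ N(−0.7, 0.35)`; age
truncated-normal 37.6 (11.4) on [18, 65]; gender 49/48/3%
female/male/diverse; a 16-item cognitive score rounded truncated-normal
8.3 (3.5).

Items: 9 per magnitude band with hyperbolic indifference points exactly
log-spaced over [0.0016, 0.25] per day; larger-later amounts span
$25–35 / $50–60 / $75–85; `k*·D` targets cycle over (0.35, 1.0, 2.8)
across neighboring indifference points so that agents near indifference
encounter short, medium and long delays — the delay diversity of the real
instrument, which is what identifies the shape of the discount curve.
Every item is emitted in both frames with identical amounts and delays;
the date frame is rendered from a configurable anchor date and differs
generatively only through ln k.

Questionnaires: 176 ordinal items across eight instruments (21+20 AD-type,
18+33+6+28 CIT-type, 9+3 split, 18+20 IIO-type; 2-, 4- and 5-point
formats), primary loadings uniform in instrument-specific ranges
(0.25–0.75), small cross-loadings U(−0.05, 0.15), factor correlations
0.45–0.55, thresholds shifted to induce the positive skew typical of
symptom scales. Factor scores correlate r ≈ 0.10 with ln k (AD, IIO; 0.04
CIT) and r ≈ 0.10 between IIO and the person-level frame effect, matching
the weak effect sizes such studies are powered for.

Passing tests on this cohort show that the pipeline recovers known
structure under its own assumptions. They do not show robustness to
features the generator omits: response styles and careless responding
beyond the factor model, item-level idiosyncrasies of the real instruments,
non-normal latent traits, order or fatigue effects, or model
misspecification of real choice behaviour (e.g., attention lapses,
amount-dependent noise).

## Problem sizes and other choices

Test and acceptance runs use deliberately scaled problem sizes chosen as
the smallest that make the statistical contracts sharp: recovery over 20
cohorts of n = 100 (2 chains × 500+400), model selection over 10 seeds at
n = 200, factor recovery at n = 2000 with all 176 items, calibration checks
with 2000 replicates. The analysis scripts default to the full emulated
cohort (800 recruited) with 2 × (600+600) draws.

Known limitations: the MH sampler, while well-mixing for these models, is
slower per effective sample than gradient-based MCMC for much larger
cohorts; PSIS-LOO on hierarchical models flags many observations
(participant-level parameters make single-observation deletion
influential), which is reported rather than hidden; the CNG test cannot
return fewer than 3 factors; polychoric standard errors are not computed
(bootstrap covers loading uncertainty).
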