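# Methods

`tempodisc` re-implements, as a tested pipeline, a cross-sectional
lifespan analysis of delay discounting: per-subject estimation of
hyperbolic discount rates from binary intertemporal choices, per-subject
power-law fits of anticipatory time perception, and a robust statistical
layer (rank correlations, MM-regression, bootstrap mediation) that links
discounting to childhood socioeconomic status (SES), life-history
strategy (LHS), chronological and subjective age, and health. Because
the motivating dataset is available only on request, the package ships a
synthetic cohort generator that emulates the study's statistical
structure; every downstream stage is validated against it.

## Models

### Hyperbolic discounting with a softmax choice rule

The present value of a delayed reward A (RMB) at delay D (days) is

    SV = A / (1 + k D),

and the probability of taking the immediate option SS is

    P(SS) = 1 / (1 + exp(-sigma (SS - SV))),

with discount rate k (day^-1) and choice sensitivity sigma (RMB^-1).
Each subject's (k, sigma) maximize the likelihood of their choices.
Numerical choices:

- The search runs in (log k, log sigma) over log k in [-9, 0] and
  sigma in [1e-6, 10]; positivity is automatic and the box covers
  indifference points for all delays the instrument uses.
- Standalone fits use a 3x3 multi-start grid polished by L-BFGS-B with
  analytic gradients. Cohort fits exploit the shared item set: the
  likelihood of every subject over a dense (log k, log sigma) grid is a
  single matrix product, and the best grid nodes seed the polish. Every
  grid node is a candidate start, so the cohort path is a strictly
  denser multi-start; the test suite verifies fitted likelihoods against
  an independent 200x200 grid oracle.
- "Failed to converge" covers: optimizer failure; log k on a search
  bound or sigma collapsed to its lower bound; all-SS/all-LL response
  patterns; and flat likelihoods, operationalized as a likelihood-ratio
  statistic against coin-flipping below the chi-square(2) 95% quantile
  (2 x gain < 5.99). The last rule flags a true random responder with
  ~95% probability by construction. Sigma at its *upper* bound is not a
  failure: that is a perfectly consistent responder whose k is pinned
  between two item indifference points.
- Estimated rates are natural-log-transformed (`log_k`) for all
  downstream statistics.
- The instrument's exact seven items are not public; the packaged
  stand-in places amounts and delays log-uniformly inside the published
  ranges (SS 840-3990 RMB, LL 2311-8190 RMB, delays 4-939 days,
  endpoints included), giving item-wise indifference points that span
  log k from -6.8 to -0.8. Any items table can be substituted.

### Anticipatory time perception

Slider readings T (mm on a 150-mm line) against calendar horizons t
(months) follow a psychophysical power law T = alpha t^beta with both
parameters constrained to [0, 5]; alpha measures overall time
contraction, beta diminishing sensitivity. The readings are fitted in
millimetres: the instrument provides no mm-to-month calibration, so
alpha absorbs the unit conversion. Fitting is robust nonlinear least
squares — a Huber loss (tuning 1.345 x MAD scale) whose scale is
re-estimated from the current residuals and iterated to convergence
(tolerance 1e-8), started from the log-log OLS line; near-exact data
fall back to plain least squares. Exclusion is two-stage: fits pinned to
a parameter bound (tolerance 1e-6), then Tukey 1.5 x IQR boxplot
outliers per parameter (applied to alpha and beta separately) among the
remaining fits. Fewer than five usable fits disables the boxplot stage
with a warning.

### Robust statistical layer

- **Kendall tau-b** with tie correction; two-sided p values from the
  tie-adjusted normal approximation (an exact permutation method is
  available for n <= 10). Association tests are rank-based throughout
  because Likert-type and behavioral measures are non-normal.
- **Huber M-estimate of location** (bend 1.28, normalized MAD scale,
  IRLS to 1e-8); reduces to the mean on clean data and to the median
  when the MAD degenerates.
- **MM-regression**: S-stage with Tukey bisquare rho at c = 1.5476
  (50% breakdown), seeded by 500 exact p-subset candidates with the best
  ten refined by I-steps (fast-S); then an M-step with bisquare psi at
  c = 4.685 (95% Gaussian efficiency) at the fixed S-scale. Standard
  errors default to the usual asymptotic sandwich
  s^2 mean(psi^2)/mean(psi')^2 (X'X)^-1 with an n/(n-p) correction; a
  fast-robust-bootstrap covariance (`cov="bootstrap"`: case-resampled
  re-IRLS of the M-step at fixed scale, 400 resamples, batched) is
  available and is what the pipeline's Models 1-2 use, because log-k
  estimates obtained from only seven binary items are near-discrete and
  the asymptotic formula underestimates coefficient spread by ~10% on
  such residuals (simulation: interaction type-I error ~11% asymptotic
  vs ~6.7% bootstrap at the nominal 5%). The reported R^2 is the
  rho-based reduction against a location-only fit at the same scale. Because the S-stage is resampling-based, refits with a
  different seed (or an augmented design) can land on solutions
  differing by a small fraction of a standard error; tests treat
  agreement within 0.25 SE as numerically identical.
- **ANCOVA F** for a group factor controlling one covariate, via nested
  OLS comparison (classical, matching how the sex effects are reported).
- **Robust mediation**: the indirect effect of X on Y through M is the
  product a x b of the X->M slope and the M->Y-given-X slope. Both path
  regressions are Huber M-regressions (tuning 1.345, iterated MAD
  scale); inference is a case-resampling (pairs) bootstrap percentile
  interval, default 2000 resamples at the 95% level. Only the indirect
  effect drives the significance flag; the direct effect is returned but
  not tested. The full high-breakdown MM-estimator can be substituted
  for the paths (`estimator="mm"`), at a substantial bootstrap cost.
  The bootstrap path fits run through a batched IRLS that solves all
  resamples simultaneously (scale frozen after five iterations,
  tolerance 1e-6) — calibration tests confirm 92-97% coverage of a true
  indirect effect at n = 200.

### Pipeline

Age groups use contiguous half-open bins [18, 34), [34, 48), [48, 70]
by default; the study's sample had recruitment gaps (18-33, 36-46,
52-69), which can be reproduced by configuring gapped cutoffs (gap ages
stay unassigned). The age-bias score is physical subjective age minus
chronological age (positive = feels older). Model 1 regresses log k on
LHS, chronological age, an age-group dummy (young = 0, older = 1) and
age x group, on young + older subjects only; Model 2 adds age bias and
age bias x group. Mediations: SES -> LHS -> log k on the whole sample;
physical health -> physical age -> log k within each group. Exclusions
are analysis-specific — a subject dropped from log k analyses still
contributes to statistics not involving log k. No multiple-testing
correction is applied (mirroring the source analysis); the report
annotates how many uncorrected tests it contains.

## The synthetic cohort

The generator emulates the published sample's structure; its defaults
are the published marginals wherever those exist, and field-realistic
choices elsewhere:

- **Sizes and marginals**: 84/54/104 subjects; per-group age,
  childhood-SES, Mini-K, health moments and sex counts as published.
  Ages are truncated normals inside the group bins. Likert-type traits
  are generated continuous and clipped (optionally discretized).
- **Trait coupling**: SES-LHS and FTP-LHS are tied through a Gaussian
  copula whose correlation is sin(pi tau / 2) for target Kendall taus of
  0.22 and 0.35, so the rank associations hold in expectation; SES and
  FTP are conditionally independent given LHS.
- **Discount-rate structure**: log k = -4.5 - 0.57 (LHS - mean LHS)
  - 0.11 (age - 24) in young, + 0.15 (age - 58.8) in older, flat in the
  middle group, + 0.12 x age-bias in the older group only, + 0.45 for
  young males, + N(0, 0.8) individual noise. The slopes are the scale of
  the published regression coefficients; the age-bias and sex couplings
  produce the published interaction and mediation sign pattern at
  realistic noise, and the noise SD leaves a structural R^2 of ~0.2-0.3.
- **Choice generation** uses the same softmax model the estimator fits,
  with true sensitivities log-uniform on [0.005, 0.05] RMB^-1. A
  fraction 7/242 of subjects are random responders (fair coin per item),
  the non-convergence analogue of the study's seven excluded
  participants.
- **Subjective ages**: physical age = chronological age + group base
  offset + 2 x (group mean health - health) + N(0, 3), so poorer health
  feels older and the age-bias/health rank correlation is negative; the
  group base offsets reproduce the published mean gaps (older adults
  feel ~5.5 years younger). Psychological age is built the same way with
  larger noise.
- **Time-perception truth**: beta ~ N(0.8, 0.15) clipped to
  [0.45, 1.15]; alpha anchors the reading at the longest horizon to a
  fraction ~N(0.6, 0.15) of the slider, coupling alpha to beta and
  keeping curves inside the instrument. Probe noise is 7 mm; 20% of
  subjects are careless probe responders (uniform slider readings),
  which the bound-hit/boxplot screen removes at a rate of the same order
  as the study's 47 exclusions.

What the generator does **not** emulate: item-level response times,
questionnaire item structure, platform effects, discretized slider use,
or any real covariance between time-perception parameters and
discounting (none is injected). A green end-to-end test therefore
establishes that the pipeline recovers the *injected* qualitative
structure — sign patterns and exclusion behavior — not that it would
reproduce the study's point estimates.

## Degenerate inputs and tie-breaks

- Constant variables make tau undefined; correlation rows are flagged
  rather than dropped silently.
- A zero MAD degrades the M-location to the median with a warning.
- Rank-deficient designs raise immediately (including Model 2 when age
  bias is literally constant at zero).
- Identical quartiles collapse the Tukey fences to a point; values *at*
  the fence are not outliers (strict inequality).
- Paired Cohen's d returns 0 for identical pairs and raises for
  constant non-zero differences.

## Known limitations

- The seven packaged choice items are a synthetic stand-in; absolute k
  estimates from only seven binary choices carry median absolute log-k
  errors around 0.3-0.4, so analyses lean on rank associations (rank
  recovery of true rates is ~0.85 tau at seven items).
- MM p-values are asymptotic; at the model subsample size (~170) the
  null-cohort tests show calibration within the tolerated 7.5%.
- The mediation bootstrap resamples cases; it does not implement the
  full Zu-Yuan robust mediation estimator, only its operational core
  (robust paths + percentile CI on a x b). Like all percentile-bootstrap
  product tests, it runs mildly anti-conservative when one path is
  strong and the other truly null (measured ~7.5% at nominal 5% with a
  tau = 0.22 first path), a known property of the method rather than of
  this implementation.
- Single mediator, no moderated mediation, no hierarchical pooling
  across subjects, no exponential/quasi-hyperbolic discounting variants.
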