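# Methods

`metaconf` implements a complete, simulation-first analysis pipeline for a
two-alternative perceptual confidence experiment: a signal-detection
generative model of choice and confidence with three post-decision
evidence-integration variants, an adaptive-staircase task simulator with a
planted individual-differences structure, per-subject metacognition metrics,
MAP model fitting by deterministic quadrature, and a group-level robust
regression battery with BIC model comparison.

## Generative model

On each trial the true side is `d ∈ {−1, +1}`.  The observer receives a
pre-decision internal sample `X_pre ~ N(d·θ_pre, 1)` and, in the
post-decision evidence task, a second sample `X_post ~ N(d·θ_post, 1)`,
where θ is the internal evidence strength in internal-noise SD units.  The
action is `a = sign(X_pre − m)` with criterion `m` (a steep softmax with
slope 1000 is the stochastic version used in the likelihood; at that slope
it is numerically a step, and an exact tie is broken by a fair coin).

The observer evaluates each sample against an assumed evidence
distribution.  In the confidence task only the low strength occurs, so the
assumed likelihood is `N(μ_low, 1)`.  In the post-decision task the two
post-decision strengths are equiprobable and the observer is agnostic about
which strength generated which sample, so both samples are evaluated under
the moment-matched single Gaussian of the mixture:

    μ  = (μ_low + μ_high)/2
    σ² = ((μ_high − μ_low)/2)² + 1      (law of total variance)

The direction log odds of a sample are the Gaussian log likelihood ratio,
which reduces to `LO_dir = 2μx/σ²`; conditioning on the action gives
`LO_correct = a·LO_dir`.  Confidence is `logistic(LO_correct_total)`,
clamped to `[1e−6, 1−1e−6]` so that log-odds round trips stay finite.

The three variants perturb the total:

- temporal weighting: `w_pre·LO_correct_pre + w_post·LO_correct_post`;
- choice weighting: the post-decision component is scaled by
  `w_confirmatory` when `sign(X_post) = sign(a)` and `w_disconfirmatory`
  otherwise;
- choice bias: `LO_bias = ±logit(w_bias)` (sign following the action) is
  added to the summed direction log odds before conditioning on the action.
  Because the sign follows the action, the increment to the correct-odds
  total is `logit(w_bias)` for either action, and it applies in the
  confidence task too (with no post-decision evidence present).

Temporal weights (1, 1) and `w_bias = 0.5` reduce both extensions exactly to
the ideal (base) model; the reduction is property-tested.

Ratings live on a 9-point grid `{0, 0.125, …, 1}` (the percent labels of
the original scale are presentation only).  A report is
`r ~ N(confidence, σ_report)`, clipped to [0, 1] and snapped to the nearest
grid point.

## Task simulator

The calibration phase is 70 trials of a 2-down-1-up staircase on the log
dot difference (asymptote √0.5 ≈ 70.7% correct), followed by the remaining
session: the converged low strength is the mean of the last 25 staircase
log strengths, and the high strength multiplies that by 1.3 in log space.
Fifty high-strength probes, yoked to the current staircase value, are
randomly interleaved after 20 burn-in trials.  Task 1 is 60 rated trials at
the low strength; task 2 is 120 trials with post-decision evidence at the
low or high strength (60/60, pseudo-randomly interleaved with runs capped
at 4; the physical post-decision evidence always favors the true side).

Unstated procedural constants were fixed once: staircase step 0.1 natural-log
units and a starting dot difference of 70 (bounds 1–312 on the 625-cell
grid with 313 reference dots).

Physical-to-internal mapping: `θ = k·(log Δ)^γ` with defaults `k = 0.065`,
`γ = 1.6`.  γ = 1.6 places the 1.3× log-strength manipulation near 80%
correct for an observer calibrated to ~71% (Φ(0.55·1.3^1.6) ≈ 0.80);
k = 0.065 puts the default observer's 70.7% threshold near the staircase
start so that 20 burn-in trials suffice for convergence, matching the
procedure the staircase emulates.  Because the staircase is self-calibrating,
k only shifts where the threshold lands within the stimulus bounds.

Missed trials are independent Bernoulli lapses (default 1%) that blank the
choice, rating and RT; confidence RTs are lognormal (median 1500 ms,
log-SD 0.4) so the 850 ms screening rule is exercisable.  A
`single_rating_collapse` switch produces degenerate raters for testing the
screening rules.

### Population structure

Factor scores are generated with unit variance and the planted structure:
political orientation `o ~ N(0, 1)`; dogmatic intolerance loads 0.37 on the
standardized `o²` term; authoritarianism loads 0.38 on `o`; their residuals
are correlated so that the dogmatism–authoritarianism correlation is 0.21.
Composite radicalism is the sum of the two z-scored factor scores.

The behavioral coupling acts on the logit of the choice-bias weight:
`logit(w_bias) ~ N(0.15, 0.4²)` with a standardized correlation of 0.18
with composite radicalism (the study-scale coefficient).  Criterion
`m ~ N(0, 0.2)`, report noise σ_report = 0.1 (the scale of its fitting
prior), psychometric gain lognormal around 0.065 (log-SD 0.2).  Age, gender
and education are independent nuisance covariates with zero true effect.
Optional couplings (e.g. to σ_report) exist but are off by default.

### What the generator does not emulate

Perceptual learning and sequential dependencies; dot-level stimulus
rendering; questionnaire item responses (factor scores are emitted
directly); any radicalism coupling other than through w_bias.  Passing
tests therefore show internal consistency of the pipeline and
recoverability of planted effects — not that human data behave this way.

## Metacognition metrics

d′ and criterion use equal-variance SDT with 0.5 added to every cell of the
2×2 count table.  meta-d′ is the maximum-likelihood estimate: the type-1
sensitivity of an ideal rater whose type-1 criterion is locked to the
subject's (scaled, meta-c = c·meta-d′/d′) and whose free type-2 criteria
best reproduce the response-conditional confidence counts under a
multinomial likelihood.  Cells are padded with `1/(2K)` where K is the
number of rating levels actually used; unused levels are collapsed, which
makes the estimator exactly invariant to monotone relabelling of the scale.
The estimand matches the Bayesian scheme used in the original analyses;
acceptance is via simulation oracles (ideal observer: meta-d′ = d′;
shuffled ratings: meta-d′ ≈ 0), not numerical identity with any particular
posterior summary.  meta-d′ is undefined (NaN, flagged) for single-bin
raters, all-correct/all-wrong subjects, or non-positive d′.

Confidence bias is mean confidence minus proportion correct by default
(raw mean confidence behind a switch — the construct is defined only up to
this choice, and the relative version is the one that is distinct from
performance).  Earnings follow the quadratic scoring rule
`1 − (accuracy − confidence)²` per rated trial.

Evidence-integration slopes are per-subject OLS fits of confidence on the
ordinal evidence code (confidence task 0, low PDE 1, high PDE 2), run
separately for correct and incorrect trials on data pooled across both
tasks; the incorrect-trial slope is sign-flipped so that larger values mean
stronger disconfirmatory integration.  Post-decision-evidence sensitivity
is the accuracy × strength interaction (accuracy ±1, strength 1/2) from
task-2 trials only, keeping it independent of task-1 measures.  These
micro-regressions are deliberately plain OLS with an intercept; robust
fitting is reserved for the group battery.

## Model fitting

Per-trial latent samples are marginalized by deterministic quadrature
rather than the original variational engine — the downstream analysis
consumes only parameter point estimates, so the estimand is the MAP under
the stated priors:

- criterion `m ~ N(0, 1)`;
- evidence strengths `μ_low ~ N(d′_low/2, 1)`, `μ_high ~ N(d′_high/2, 1)`,
  anchored to the subject's observed d′ at each strength (the high-strength
  d′ comes from the 50 calibration probes);
- report noise σ_report ~ half-normal(0.1);
- weights `~ N(1, 1)`; choice bias `w_bias ~ N(0.5, 1)` evaluated on the
  probability scale but optimized on the logit scale (no Jacobian term —
  penalized ML in the probability coordinate).

The task-1 likelihood is a 1-D integral of the pre-decision sample over the
half-line selected by the choice; it is computed with Gauss–Legendre nodes
placed in the truncated normal's CDF, which keeps the integrand smooth
wherever the criterion sits.  Task-2 likelihoods add a Gauss–Hermite
integral over the post-decision sample.  Trials collapse into
(side × choice × evidence level) cells with rating counts, so the cost of a
likelihood evaluation is independent of trial count.  Default resolution is
61 nodes per dimension; population-scale analyses in the
test and acceptance suites use 13–21 nodes per dimension, which changes
recovered parameters by well under the parameter-recovery tolerances.
Grids below 9 nodes per dimension are refused.

Rating likelihood: the source model treats the snapped rating as a
continuous Gaussian observation.  That density form is retained
(`rating_mode="density"`) but is ill-posed for point estimation: snapped
ratings pile up at the scale endpoints, so the density likelihood rewards
σ_report → 0 with unbounded spikes (the degenerate point beats the truth by
tens of log units even under exact quadrature).  The default fitting
likelihood is therefore interval-censored: the Gaussian report density is
integrated over each snap bin (outer bins absorb the clipping tails).  The
binned likelihood recovers σ_report and w_bias correctly and is the
statistically appropriate treatment of a discretized report.

Optimization is multi-start L-BFGS-B (bounded; `w_bias` via logit).  The
informed start uses the d′-anchored strengths and prior-mean weights;
`fit_subject` defaults to 5 starts, while population-scale fits use 1–2
informed starts — the objective proved smooth enough that extra restarts
reproduce the same optimum, and the saving is what makes the
model-recovery studies tractable.  Convergence diagnostics, a Laplace
covariance (inverse numeric Hessian of the negative log joint) and a
`summary()` table live on the results object.

Report noise is tied at the population level: `fit_population` estimates a
single σ_report (median of free-σ base-model fits on a pilot subsample) and
fixes it for every per-subject variant fit, mirroring the group-level
report-noise parameter; fitting it per subject remains available.  An
optional hierarchical mode iterates empirical-Bayes updates of the group
means/SDs of criterion and weight priors to a fixed point, shrinking
subject estimates toward the group mean.

Posterior predictives draw parameter vectors from the Laplace approximation
(100 draws, 4000 trials per condition by default; a single draw degenerates
to the MAP point prediction) and aggregate confidence by condition ×
accuracy, with a top-decile/rest split on composite radicalism.

## Group-level battery

All battery regressions are robust IRLS fits with Tukey bisquare weights
(tuning constant 4.685) on z-scored outcome and predictors, so the
coefficients are standardized betas; z-scoring happens before robust
weighting.  SEs come from the IRLS fit at convergence; p-values are normal
two-tailed, with a one-tailed option that halves the p when the sign
matches a declared direction.  Per-predictor R² is the drop in explained
variance on removing the predictor (robust refits); VIFs are screened
against the standard cut-off of 10.  Regression BIC is the Gaussian
`n·ln(RSS/n) + k·ln(n)` with k counting slopes, intercept and error
variance — a convention that only matters through ΔBIC within a comparison.

The variant comparison regresses composite radicalism on (μ_low, μ_high)
plus each variant's weight parameter(s), including the single-weight
reductions of the temporal and choice-weighting models so that the
choice-bias model cannot win on parameter count alone; the table reports
BIC minus the minimum (the best model sits at exactly zero).

Exclusion screening applies the four strict behavioral filters before any
group analysis: task accuracy above 85% or below 60%, a single rating more
than 90% of the time (computed after dropping missed trials), median
confidence RT below 850 ms, and more than 5% missed trials.

## Problem sizes and numerical choices

The test and acceptance suites run at desk scale, chosen as the package's
own defaults: staircase targets use 100 observers × 200 trials;
likelihood oracles use 10⁵-trial simulations against 61×41-node quadrature;
parameter recovery uses 50 subjects at the study's 180 trials (plus one
10⁴-trial subject); the model-comparison recovery study uses 20 seeded
replicates of 120-subject populations; the qualitative radicalism battery
uses one 400-subject population (the scale of the original samples).
Degenerate inputs (empty datasets, single-bin raters, missing accuracy
classes, rank-deficient designs, perfect collinearity) raise or flag as
documented in each docstring.

## Known limitations

- The choice-bias mechanism, at evidence strengths dictated by ~71%
  calibrated accuracy and bias increments below ~logit(0.8), elevates
  incorrect-trial confidence and compresses the confirmatory (ceiling-side)
  integration slope, but does not reduce the disconfirmatory slope — that
  reduction only emerges at extreme bias (w_bias ≳ 0.85).  Statements about
  human disconfirmatory integration should not be read off this synthetic
  world.
- The regression-based variant comparison has modest power at population
  sizes below several hundred subjects, because the other variants' fitted
  weights are strong statistical proxies for the generating choice-bias
  parameter; the comparison is decisive only in the large-n limit.
- MAP + Laplace is a point approximation; full-posterior uncertainty is out
  of scope (the optional draws come from the Gaussian approximation).
- The meta-d′ estimator assumes equal-variance SDT and a response-locked
  criterion ratio; unequal-variance generalizations are not implemented.
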