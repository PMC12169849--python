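# Methods

This note documents the models, the synthetic-data generator, the
numerical machinery and the open design choices behind `effortdm`.

## The task

The simulated task is a gamified effort-expenditure paradigm for remote
testing. A clicking calibration (three 10 s repetitions; capacity = mean
of repetitions 2 and 3, clicks per 10 s) anchors four effort levels:
clicking at 30/50/70/90% of capacity sustained for 8/11/14/17 s. The main
task presents 64 binary offers (accept/reject) in four blocks of 16. Each
offer pairs an effort level E ∈ {1..4} with a reward R ∈ {2..5} points.
Offers are scheduled by 16 interleaved staircases whose start offers
enumerate the full 4×4 grid; acceptance makes a staircase harder
(E+1 or R−1, one dimension per step), rejection easier (E−1 or R+1).
Rejection always pays 1 point; a successful accepted challenge pays R, a
failed one 0.

Where the task description leaves details open, the simulator fixes them
as follows (all configurable):

* required clicks = ⌈fraction × (capacity/10) × duration⌉, floor one click
  (`rounding` accepts floor/round as alternatives);
* tie between the two feasible staircase moves: uniform 1/2 from the
  session RNG;
* at a corner where no move is feasible (accept at E=4,R=2; reject at
  E=1,R=5) the offer repeats;
* each block is a seeded permutation of the 16 staircases, so every
  staircase appears exactly once per block;
* a failed accepted challenge pays 0 points (failures are rare by design);
* the practice-phase capacity re-adjustment is exposed only as
  `SessionConfig.capacity_override`;
* rejection waiting times are matched to the effort level but carry no
  term in the decision model (no delay discounting).

Challenge outcomes come from a Gaussian motor model: clicks in a challenge
are `round(Normal(rate × duration, rate_sd × √duration))`, truncated at 0,
with default sustained rate 0.97 × the calibrated burst rate and
`rate_sd` 0.8 clicks/s. These defaults put the success rate of accepted
challenges in the ~99% range, i.e. the regime the calibration procedure is
designed to produce (reported success in the original task ≈ 98.7%).

## Model space

Offers enter the models standardized: e = E/4, r = R/5, both in (0, 1].
Subjective value and choice probability are

    SV = β_R · r − cost(e),      p(accept) = 1 / (1 + e^−(α + SV))

with cost(e) = β_E·e (linear), β_E·e² (parabolic) or β_E·(e^e − 1)
(exponential; chosen so cost(0) = 0, and configurable since the exact
published form of the exponential family is not available to us). Nine
models cross the three costs with three parameter configurations: {β_E},
{β_E, β_R}, {α, β_R, β_E}. Excluded parameters are fixed (α = 0, β_R = 1),
so reduced models are exact restrictions of the full model — the nesting
is asserted trial-by-trial in the tests. β_R and β_E live on the positive
half-line (β ≥ 0 is accepted at the boundary so that cost-free edge cases
are computable); α is unconstrained.

## Hierarchical inference

Subject-level parameters get a non-centered hierarchy: for each free
parameter, `subject value = group mean + group SD × subject offset`, with
an identity link for α and a log link for β_R, β_E. Priors: group means ~
Normal(0, 1), group SDs ~ half-Normal(0, 1) (on the sampler scale),
offsets ~ Normal(0, 1) — weakly informative on the standardized offer
scale. Posterior means of positive parameters are computed by
exponentiating per draw and averaging.

Sampling uses the package's adaptive Hamiltonian Monte Carlo
(`effortdm._hmc`): leapfrog integration with a diagonal mass matrix,
dual-averaging step-size adaptation (target acceptance 0.8–0.85), two
mass re-estimations during warmup, and a jittered trajectory length
(base 32 leapfrog steps) to decorrelate draws. Gradients are analytic and
vectorized over trials, so a fit of 100 subjects × 64 trials × 4 chains ×
(1000 warmup + 2000 draws) takes roughly two minutes on one core.
The default `MCMCConfig` mirrors the reference protocol (2000 warm-up,
6000 sampling iterations, four chains); the tests, the pipeline and the
acceptance script run scaled-down configurations (400–2000 draws per
chain) chosen as the package's own desk-scale problem sizes — at those
sizes well-specified fits reach split R-hat ≤ 1.01 with bulk ESS in the
hundreds.

Convergence is gated twice: a fit *fails loudly* (raises) if any split
R-hat exceeds 1.05, and reports `converged = (max R-hat ≤ 1.01)` — the
standard gate, stricter than needed for the regimes we simulate. Fully
degenerate data (every decision identical across all subjects) raise
`DegenerateDataError` instead of producing an unidentified fit.

Model comparison uses PSIS-LOO on the pointwise log-likelihood draws
(`arviz.loo`), reporting ELPD ± SE and LOOIC = −2·ELPD (an exact identity
in the code), with Pareto-k̂ > 0.7 counts surfaced as warnings; refitting
problematic observations is out of scope. Below 10 posterior draws the
PSIS smoothing is undefined and the implementation falls back to the
exact log-mean-exp limit, which for a single draw reduces to the sum of
pointwise log-likelihoods — that analytic limit is asserted in the tests.
The pointwise log-likelihood store is thinned to at most
`loglik_max_draws` (2000) draws to bound memory.

Posterior predictive checks re-simulate every observed trial from thinned
posterior draws (500 by default) and compare observed to predicted
per-subject acceptance proportions by effort level and by reward level;
R² is the squared Pearson correlation across subject × level cells.
Parameter recovery simulates agents from known parameters (defaults match
the calibrated study conditions below), refits, and reports Pearson
correlation, bias and RMSE of posterior means against the generating
values on the natural scale.

### A note on the PPC R² ceiling

With 64 trials per subject, each subject × level cell holds ~16 trials,
i.e. binomial noise with variance ≈ 0.012 on the observed proportion. At
the between-subject acceptance spread the generator is calibrated to
(SD ≈ 0.15), an *oracle* predictor that knows the true generative
probabilities reaches only R² ≈ 0.84 (effort marginal) / 0.77 (reward
marginal) at n = 100; the fitted model scores in the same range or
slightly above (≈ 0.86–0.91 effort, 0.77–0.84 reward across seeds)
because its posterior partially conditions on the very decisions being
predicted. Values much above that are only reachable with substantially
larger between-subject heterogeneity or more trials per cell. The
mismatch contrast (a deliberately wrong model scores clearly lower on
both marginals) is the diagnostic that carries information at this scale.

### β_R identifiability

Standardized rewards span only 0.4–1.0 across four levels, so the
likelihood pins down the combination α + r̄·β_R much more tightly than
β_R itself: in recovery studies that combination is recovered with
correlation ≈ 0.88 while the α and β_R posterior-mean errors
anticorrelate (≈ −0.5) and the β_R correlation sits near 0.5. This is a
property of the design, not of the sampler; recovery of β_R improves
mechanically with wider generating spread or a larger reward range.

## Synthetic cohorts

`synthetic_data.generate_population` draws agents and a covariate table
with the dependence structure the downstream analyses assume:

* decision parameters: α ~ Normal(1.4, 1.0); β_R, β_E ~ moment-matched
  lognormals with mean 2.0 and SD 0.8 (natural scale). These group values
  are calibrated so simulated cohorts land in the published acceptance
  regime (subject-mean acceptance ≈ 77%, between-subject SD ≈ 15%);
* a latent one-dimensional symptom factor loads on SHAPS (+0.7) and, with
  flipped native direction, on DARS and AES (−0.7), and on α with weight
  −0.18 (more severe symptoms → lower acceptance bias);
* chronotype (early/intermediate/late at 10/80/10%) with internally
  consistent MEQ sums and free-day mid-sleep times, so the threshold
  classifier recovers the class exactly; late chronotype shifts β_R by
  +1.7 and α by −0.8, and a synchrony term +1.4 × late × evening restores
  the α deficit at the preferred time of day. These four effect weights
  are calibrated so that min–max-standardized GLM coefficients at
  n ≈ 950 match the reference magnitudes (≈ −0.11 for SHAPS→α, ≈ −0.11
  and +0.19 for the chronotype main and interaction effects on α,
  ≈ +0.3 for chronotype→β_R);
* instrument scales (SHAPS 0–36 mean 9.15 SD 6.28, DARS 0–68, AES 18–72,
  MEQ 16–86, BMI, FINDRISC) with range clipping counted and reported in
  `covariates.attrs["clipped_counts"]`.

All generative truths (parameters, factor scores, chronotype class) are
stored with the table; identical config + seed reproduce bit-identical
outputs. `generate_testretest` replays each agent twice with session-level
parameter jitter (additive SD 0.25 on α, multiplicative log-SD 0.15 on the
sensitivities); jitter 0 reproduces exact parameter stability.

What the generator does *not* emulate: item-level questionnaire responses,
reaction times, within-session learning or fatigue effects on decisions,
missing data, and any correlation between motor capacity and decision
parameters. Passing tests therefore demonstrate that the pipeline recovers
structure *of the kind assumed*, not that real data contain it.

## Downstream statistics

* **Exclusions** are applied in a fixed order (neurological/language flags,
  catch questions — fail ≥ 1 easy or both hard —, all-reject subjects,
  calibration capacity < 7, within-calibration spread, pre→post capacity
  change). The two "> 3 SD" rules use a robust cohort threshold
  (median + 3 × MAD-σ) so that re-applying the report to its survivors
  excludes no one; subjects with missing calibration are flagged, not
  crashed on.
* **Effort × reward tests** run on subject × cell acceptance proportions
  with *numeric* effort and reward predictors and their product
  (single-df F tests, denominator df = cells − 4). Cells are weighted by
  their trial counts and predictors are mean-centred: the adaptive
  staircases make cell coverage extremely unbalanced (corner cells
  accumulate visits), and without weighting/centring the F tests are
  badly miscalibrated under a coin-flip null. Note that between-subject
  selection induced by the staircases attenuates the *reward* main effect
  in heterogeneous cohorts — who reaches a high-reward cell is not random.
  A trial-level logistic alternative is deliberately out of scope.
* **Min–max standardization** maps covariates and parameters to [0, 1];
  DARS, AES and MEQ are direction-flipped first so higher always means
  more severe / later.
* **PLS linkage** (scikit-learn) splits 75/25, picks the component count
  (0 = intercept-only is a candidate and may win) by 10-fold CV-RMSE on
  the training part, evaluates out-of-sample RMSE on the held-out part,
  and runs a permutation test (1000 permutations, p floored at
  1/(n+1)) re-fitting at the selected component count per permutation.
  Component 1 is oriented so its outcome loading is positive, making
  predictor weights signed like their association with the outcome.
* **Bayesian GLMs** are Gaussian linear models Gibbs-sampled under
  Normal(0, 1) coefficient priors (diffuse for the intercept) and a vague
  inverse-gamma noise prior, adjusting for mean-centred age and binary
  gender; a coefficient is "credible" when its 95% HDI excludes zero. The
  stopping rule for sequential data collection is met when every
  monitored HDI width is ≤ 0.20 (boundary inclusive); an empty monitor
  set is an error.
* **Chronotype**: early iff MEQ > 58 and mid-sleep before 02:30; late iff
  MEQ < 42 and mid-sleep after 05:30; otherwise intermediate. Mid-sleep is
  taken directly as the free-day value (no chronotype-corrected MSFsc).
* **Test–retest**: ICC(3,1) (two-way mixed, consistency, single measure,
  via pingouin) per parameter, plus cross-session prediction: session-A
  posterior means score session-B choices (summed Bernoulli
  log-likelihood and % correct), against chance (p = 0.5) and against
  group-mean parameters, by paired one-sided t tests.
* **Case–control matching** is a greedy nearest-age exact-gender utility.

## Known limitations

* The HMC sampler uses a fixed (jittered) trajectory length, not NUTS;
  posteriors with much heavier funnels than these hierarchies may need
  longer trajectories or more warmup.
* The exponential cost form is a convention (`β_E·(e^e − 1)`); ranking
  results involving the exponential family depend on it.
* PLS permutation power at desk-scale effect sizes is modest; the test
  suite asserts calibration (null super-uniformity) and the loading
  pattern, not significance at small n.
* ICC p-values come from the standard F approximation and are not
  permutation-based.
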