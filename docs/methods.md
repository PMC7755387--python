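# Methods

This note documents the models, the numerical choices, and what the
synthetic-data experiments do and do not establish.

## Task schedules

Schedules are exact, not merely in expectation: within every
consecutive 10-trial sub-block the current best car wins on exactly 8
trials, with the win positions a uniformly random permutation under the
seed. An 80-trial schedule therefore has a best-car win rate of exactly
80%. Volatile schedules hold the best car fixed within 20-trial blocks
and flip it at trials 21, 41 and 61 (1-based); the initial best car is
a seeded coin flip. Reward pairs are drawn uniformly with replacement
from the fixed list (10–10, 10–40, 10–60, 10–80, 20–40, 40–10, 40–20,
40–40, 60–10, 80–10), read as (left option, right option); because
screen side is cosmetic — beliefs attach to car identity — only the
pair multiset matters for modelling, but side assignments are generated
anyway, swapping every 6–10 trials. Happiness probes are placed with
independent uniform gaps of 3 or 4 trials (20–26 probes per session).
Stimulus timing, practice trials and instruction screens are out of
scope.

## Choice models

A single latent belief p₁ (probability that car 1 wins) is tracked;
because exactly one car wins and the outcome is shown regardless of
choice, car 2's belief is the complement and one delta-rule update per
trial serves both cars. Beliefs start at 0.5 at the start of each
environment and are not reset at (unsignalled) reversals. The belief
recursion is evaluated as a linear filter, so likelihoods are cheap and
exactly reproducible.

Selector details and deliberate choices:

* Rewards are normalised by 80 (the maximum offer) in the additive
  selector, and likewise in the multiplicative selector. The latter is
  a numerical necessity as much as a convention: with raw points the
  logistic argument β·ΔEU reaches several hundred over most of the
  bounded parameter box, every optimiser start lands on a saturated
  plateau, and the fit is meaningless. Normalisation also gives β the
  same scale in all four selectors.
* The multiplicative distortion applies the clip *after* the linear
  transform: `clip(η·(P−0.5)+0.5, 0, 1)`; at η=1 it is the identity.
* Bounds: α ∈ [0,1], β ∈ [0,50], φ ∈ [0,1], η ∈ [0,10].
* Fitting: 10 uniform-random starts inside the box, L-BFGS-B with
  function tolerance 1e−8, best local optimum kept. Refits are
  deterministic given the seed.
* Pseudo-r² is McFadden's, 1 − LL/(n·ln½), against the coin-flip
  chance model. Degenerate sessions (a single repeated choice) are
  rejected rather than fitted.

## Happiness models

Eleven models share the form `w₀ + Σ w·(decayed history)` with one
forgetting factor γ per model. Decayed sums run over *all* trials 1..t
— rated or not — and a rating is attributed to the most recent
completed trial, whose outcome the subject has just seen. Subjective
terms (P̂, PPÊ, EV̂, RPÊ) replay the learner at the additive-model
fitted α for that session; objective terms use the scheduled 0.8/0.2
contingency of the chosen car. Rewards are the *obtained* reward (0 on
losses): rescaled to [0,1] inside prediction-error terms, raw points in
the reward-history models, whose reference point RP is bounded in
[0, 80] points. Win/loss weights are unbounded (they are empirically
anticorrelated across subjects, so no positivity constraint is
imposed).

Fitting profiles out an i.i.d. Gaussian noise scale. For fixed γ the
weights solve by least squares (the reference-point model is
reparameterised as two linear regressors, RP recovered as a ratio); γ
is optimised on a 0.01 grid plus bounded local refinement, which the
joint-then-separate two-environment protocol (joint fit supplies the
starting γ for per-environment refits) complements rather than
replaces. Ratings are z-scored within subject and environment by
default (sample SD, ddof=1); raw-rating fits bound w₀ in [0, 100] via
bounded least squares and are used for baseline-mood analyses. The
noise SD is profiled, not counted, so parameter counts are 3 for
single-term models and 4 for two-term and reference-point models (w₀
and γ included). BIC uses the concentrated Gaussian log-likelihood with
its 2π constant; the constant cancels in every comparison, which is all
BIC is used for. Fewer than 5 ratings is an error; zero rating variance
and near-flat γ profiles are returned as flagged fits.

Two known interpretation choices: the bound-[0,10] multiplicative
parameter is treated as a single distortion/risk parameter η, and the
"how many past trials matter" gloss of γ is not operationalised — the
package reports γ itself.

## Model comparison

Fixed effects: per-model BIC summed over subjects, reported as ΔBIC
against a reference model. Random effects: log model evidence is
approximated by −BIC/2 per subject and fed to the variational Dirichlet
scheme (uniform prior α₀=1, subject-wise posterior model probabilities
∝ exp(log evidence + ψ(α_k) − ψ(Σα)), iterated to 1e−8). Exceedance
probabilities are Monte-Carlo argmax frequencies over 10⁶ Dirichlet
draws, giving MC error below 0.001; EP > 0.95 is treated as decisive.
Protected EP, Bayesian omnibus risk and family inference are not
implemented.

## Synthetic cohorts

The generator produces what the analyses assume: 75 subjects × two
80-trial environments, choices from the additive selector, ratings from
the probability + PPE happiness model on the agent's *own* belief
trace, and an integer 0–27 symptom score. Population distributions are
truncated normals centred on the group means with SD = SEM·√75 from the
printed group statistics (stable α 0.16 ± 0.02 SEM, volatile α
0.47 ± 0.03, φ 0.57/0.44, w_P 0.74/0.94, w_PPE 1.32/1.14, γ 0.59/0.63,
baseline mood 55.0/49.5 rating points). β is fixed at 10 (no group SEM
is available for it). Truncation shifts means slightly — e.g. the true
volatile-minus-stable α contrast averages ≈0.27 rather than 0.31 —
which the recovery tests account for by scoring against the realised
truths. γ is drawn once per subject and shared across environments
(forgetting is trait-like); `shared_gamma=False` gives independent
draws. Cross-subject independence is assumed for all other parameters.

**Rating noise.** Fitted happiness weights are defined on z-scored
(unit-variance) ratings, so the only generator consistent with their
meaning makes the generated z-scale series have unit variance: the
default calibration sets each subject's noise variance to
1 − var(model prediction). Under it the model explains ≈0.5 of rating
variance at the stable group means — inside the printed per-model
range — and recovered weights are on the generating scale. Calibrating
noise to force a specific r² instead (available as
`noise_calibration="target_r2"`) changes the total variance of the
series and rescales every recovered weight by 1/SD; with the realised
signal variance here that inflates weights by ≈19%, which is why it is
not the default. Raw ratings are produced as
w₀ + 15·(prediction − mean + noise), clipped to [0, 100]; the 15-point
scale factor approximates the printed rating SDs (~24–25) and clipping
affects <5% of ratings at defaults.

**Symptom coupling.** Baseline mood has a trait component shared across
environments (correlation `w0_trait_corr`, default 0.65) plus a
volatility-specific component; the symptom score couples through a
Gaussian copula (latent r = 2·sin(πρ/6)) to the volatility-specific
component only, targeting a Spearman ρ of −0.28 with the volatile
baseline. This structure — rather than independent baselines — is
forced by the observed pattern it emulates: the symptom correlation is
absent in the stable environment, present in the volatile one, and
*strongest* for the standardised volatile-minus-stable difference,
which is impossible unless differencing removes shared trait variance.
Symptoms map the latent normal through a Poisson(5) quantile function
clipped to 0–27, giving a right-skewed integer score typical of
community depression questionnaires.

## What the recovery experiments show — and don't

Passing recovery at the group-mean parameters shows the estimation
machinery is unbiased and the models identifiable *under the generating
assumptions*: additive choices, ratings truly produced by the
probability + PPE model, Gaussian noise, independence across trials.
Real raters drift, use scale anchors idiosyncratically, and may mix
strategies mid-session; none of that is emulated, so recovery success
here does not certify parameter accuracy on human data — it certifies
that failures there would not be artefacts of the fitting code. The
cohort experiments use 75 subjects and 80 trials per environment,
matching the study design they stand in for.

## Known limitations

* Log evidence is the Schwarz (−BIC/2) approximation, not a Laplace or
  free-energy evidence; exceedance probabilities inherit that choice.
* Happiness weight recovery is noisy at the single-subject level
  (~22 ratings; the two weights of the probability+PPE model trade
  off); only cohort-level means are calibrated.
* The learner assumes full outcome observability and complementary
  beliefs; tasks with independently rewarded options need a two-state
  learner the package does not provide.
* No hierarchical estimation: parameters are per-subject point
  estimates, with random-effects treatment only at the model-selection
  stage.
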