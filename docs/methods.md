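# Methods

## The model

A two-alternative value-based choice starts from prior value beliefs:
independent Gaussians per option with modes μ₁⁰, μ₂⁰ and a shared
**variance** σ₀ (everywhere in this package σ denotes a variance, never a
standard deviation — a common source of confusion worth stating up
front).  Investing an amount z of cognitive resources has two anticipated
effects, split equally across the two options:

1. precision growth (type #1 efficacy β): σ(z) = 1/(1/σ₀ + βz), the form
   of a Gaussian-likelihood Bayesian update with likelihood precision βz;
2. mode perturbation (type #2 efficacy γ): each mode moves by
   δᵢ ~ Normal(0, γz), so the mode difference Δμ receives
   Δδ ~ Normal(0, 2γz).

Choice confidence given a belief state is the probability that the
preferred option truly has the higher value,
Pc = s(π|Δμ|/√(3(σ₁+σ₂))) with s the logistic sigmoid; this uses the
standard moment-matching replacement of the Gaussian CDF,
Φ(x) ≈ s(πx/√3).  Before investing, the controller can only anticipate
confidence by integrating over the unknown perturbation.  |Δμ₀ + Δδ| is
folded-normal, with (moment-matched) mean

    E[|Δμ| | z] = 2√(γz/π)·exp(−Δμ₀²/(4γz)) + Δμ₀·(2·s(πΔμ₀/√(6γz)) − 1)

variance V[|Δμ| | z] = 2γz + Δμ₀² − E², and anticipated confidence

    P̄c(z) = s( π·E[|Δμ||z] / √(6·(σ(z) + V[|Δμ||z]/2)) ).

The allocation is z* = argmax R'·P̄c(z) − α'z with condition-dependent
importance and cost: R' = R·kR on consequential trials (multiplicative,
keeping kR a unitless importance boost), α' = α + kAlpha on penalized
trials (additive, an extra cost per resource unit).  The corollary
outputs are the reversal probability Q(z*) = s(−π|Δμ₀|/√(6γz*)), the
expected spreading of alternatives SOĀ(z*) = 2√(γz*/π)·exp(−Δμ₀²/(4γz*))
(a truncated-normal first moment, exact), and the certainty gain βz*.
At γz = 0 the limits are Q = SOĀ = 0, E[|Δμ|] = |Δμ₀|, V = 0.

### Accuracy of the closed forms

The sigmoid stand-in for Φ carries absolute error up to ≈0.023 near
argument |Δμ₀|/√(2γz) ≈ 0.7.  Consequently E[|Δμ||z] can deviate from the
exact folded-normal mean by up to 2|Δμ₀|·0.023 (and can dip marginally
below |Δμ₀|), and Q by up to ≈0.023 from the exact Gaussian tail.  SOĀ is
exact.  The test suite pins the implementation to exact-CDF references
within these budgets, and to Monte-Carlo oracles; tolerances tighter than
the approximation error cannot be met by these formulas, whatever the
implementation.  Relatedly, P̄c(z) is *not* strictly increasing in z when
β = 0: a 2×10⁶-draw Monte-Carlo of the exact expectation shows a shallow
dip (order 10⁻⁴) at small γz before the rise — deliberation first spreads
|Δμ| toward zero about as often as away from it.  With β > 0 the
precision channel dominates and monotonicity holds on all tested grids.

### Optimizer

z* has no closed form.  The reference optimizer scans a uniform grid
(512 points on [0, z_max]) and refines the best cell with bounded scalar
minimization (tolerance 1e−7), taking the smallest argmax on ties and
warning when the optimum touches z_max.  The fitting and simulation hot
path uses a vectorised variant (385-point grid + three-point parabolic
refinement) accurate to ~1e−3, which is far below every quantity's
sensitivity to z.  z_max defaults to 20 resource units, large enough that
under the default populations fewer than 0.1% of trials are truncated.

## Observation model

Trial inputs come from the pre-choice reports: Δμ₀ = VR⁰_a − VR⁰_b and
σ₀ = 1/max(VCR⁰, ε) with VCR⁰ the mean certainty rating and ε = 0.01
flooring the degenerate all-zero-certainty case.  Five continuous
observables are affine transforms of latent outputs — confidence ← P̄c(z*),
spreading ← SOĀ(z*), certainty gain ← βz*, log-RT ← z*, effort ← z* —
each with intercept, positive slope and Gaussian noise SD; response time
is modelled on the log scale.  Change of mind is Bernoulli with the
unmapped Q(z*) (an affine map of a probability would not stay a
probability), with the success rate clamped to [1e−6, 1−1e−6] so a
structural zero meeting an observed reversal costs a finite penalty.
Observed spreading and certainty gain are computed from ratings by the
analysis module (chosen-minus-unchosen difference change; mean post-minus-
pre certainty change — the mean, not the sum, with a switch).

## Simulator

`simulate.SimConfig` emulates the study design: 41 subjects, 74 trials
each (60 neutral, 7 consequential, 7 penalized, shuffled), ratings on
[0, 1].  Value ratings are iid Beta(2, 2) (broad, centred); certainty
ratings are iid Beta(1.2, 1.2), a nearly flat distribution chosen so that
prior certainty varies enough to drive the certainty-mediated effects.
Subject parameters are log-normal around medians α = 0.02, β = 0.2,
γ = 0.025, kR = 1.3, kAlpha = 0.1 with log-SD 0.2 (R is fixed at 1; its
scale is absorbed by α and the output maps).  Observation noise SDs are
0.08 (confidence), 0.05 (spreading), 0.05 (certainty ratings), 0.25
(log-RT), 0.08 (effort).  These values were fixed once so that the
simulated cohort lands in empirically reported ranges — median RT of a
few seconds, reversal rate of order 15–25%, mean certainty gain ≈ 0.1 —
and produces the canonical sign pattern of the model-free regressions.

Realisation follows the generative story exactly: z* from the
controller, δ draws with variance γz*, choice = sign of the post-effort
mode difference (exact ties break uniformly), post-choice value ratings =
clip(pre + δ) (the identity-plus-clip read-out is isolated in
`value_to_rating` and is a stand-in — the latent-value-to-rating map is
not empirically constrained), post-choice certainty = clip(pre +
affine(βz*) + noise), reported confidence = the belief-state confidence at
the realised Δμ(z*) plus noise.

What the simulator deliberately does **not** reproduce: rating
test–retest noise (hence essentially no "error" trials — choices
contradicting both pre- and post-choice preferences — where real cohorts
show ~12%), regression-to-the-mean in certainty ratings (which inflates
the empirical certainty-gain/VCR⁰ association), gaze or attention
channels, and item-identity structure.  Passing tests therefore validate
the pipeline under the model's own assumptions, not the model against
real behaviour.  Two further realism gaps are documented rather than
hidden: the simulated reversal rate (~20%) and mean spreading (~0.2
rating units) run above typical empirical values, a side effect of
making the certainty-mediated channels strong enough to detect at this
design size.

## Fitting

Per subject, the estimation target is the posterior mode of
θ = (log α, log β, log γ, log kR, log kAlpha, log gain-slope) under
Gaussian priors (default location 0, scale 2 — weakly informative; prior
moments are configurable through `PriorSpec`).  Two identifiability facts
shape the parameterisation:

* **Scale gauge.**  The model has an exact symmetry: (α, β, γ, kAlpha) →
  λ·(α, β, γ, kAlpha) with z → z/λ changes no observable distribution,
  because the affine output maps absorb the unit of z.  The package
  measures z in log-RT units: the log-RT map's slope is fixed at 1
  (falling back to the effort map when RT is not fitted).  Fitted rate
  parameters are therefore "per log-RT unit"; recovery metrics use rank
  correlations, which ignore the resulting unit conversion.
* **Gain slope.**  The certainty-gain observable is slope·βz*: a freely
  profiled slope absorbs β entirely, so the gain slope is estimated
  jointly under its prior rather than profiled.

All remaining nuisances (intercepts, other slopes, noise SDs) are
concentrated out in closed form (per-variable least squares given the
latent predictions, slope floored at 1e−6, noise SD floored at 1e−3), so
the search runs in six dimensions.  Optimization is multi-start
Nelder-Mead: a coarse global scan over several decades of (α, β, γ)
scored with the gain slope profiled, the best three points (carrying
their profiled slope as the start value) plus two fixed fans and seeded
jitter, followed by restarted-simplex polishing.  The Laplace covariance
comes from a central-finite-difference Hessian (step 1e−4, eigenvalue-
clipped to PSD), and the log evidence from the standard Laplace formula.
Non-convergence is flagged on the result, never raised.

This MAP + Laplace scheme targets the same posterior mode as a
variational-Laplace fit but does not iterate variational updates; its
covariance is the local curvature only.

## Out-of-sample protocol and recovery

Fits on the decision-related variables (confidence, change of mind,
spreading, certainty gain) predict the effort-related ones (log-RT,
effort) and vice versa; held-out predictions are latent (unmapped), and
accuracy is the within-subject across-trial Pearson correlation, which is
invariant to the missing affine maps.  Chance levels are the 95th
percentile of group-average correlations after shuffling predictions
across trials within subject (≥200 permutations).

`parameter_recovery` simulates subjects, refits them, and reports
truth-vs-estimate Spearman correlation, bias and RMSE on the log scale
(bias includes the gauge's unit conversion).  Truths are drawn with
log-SD 0.4 around the population medians — wider than the within-study
spread, because a recovery study should probe the estimator across the
plausible range, yet narrow enough to avoid degenerate regimes (very
small α saturates effort on every trial; very large α yields none;
both are uninformative).  The harness uses priors matched to its own
generating population (the well-specified setting).  At 74 trials per
subject the unitary cost recovers well (rank correlation ≈ 0.8–0.95);
the two efficacies recover more weakly (≈ 0.6–0.8 depending on the
seed) because β acts only through the confidence precision term and the
prior-constrained gain channel, and trades off against γ inside the
confidence formula.  This dispersion was verified to be a property of
the posterior, not of the optimizer: apparent mis-recoveries have better
posterior density than the generating truth.

## Analyses

`observed_frame` builds the six dependent variables from a trial table;
tied rating comparisons are excluded from change-of-mind classification
(flagged, not silently dropped).  Standardized regressions z-score the
outcome and the continuous regressors (|ΔVR⁰|, VCR⁰) within subject;
condition dummies enter raw as 0/1; a constant outcome (e.g. a subject
with no reversal) contributes zero weights.  Group-level inference is a
one-sample t-test per weight across subjects, one- or two-sided per
contrast.  Binned summaries median-split VCR⁰ within subject, crossed
with five within-subject quantile bins of |ΔVR⁰| (configurable), and
average cell means across subjects.

## Problem sizes used by the reproduction script

Monte-Carlo oracles use 10⁶ draws over a 5×5×5 grid; the optimizer check
uses 100 random parameter sets against a 10⁵-point exhaustive scan;
cohort statistics average five replicate 41×74 experiments (replication
reduces the Monte-Carlo error of weak group-level effects whose true
magnitude is a few hundredths of a standardized weight); recovery uses
20 subjects; the prediction protocol fits 8 subjects under three
variable subsets.  These sizes make the full script a single-core run of
a few minutes.
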