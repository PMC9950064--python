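# Methods

This note documents the models, defaults and design choices behind
painlearn, in the package's own terms.  Everything quantitative stated
here is computed by the test suite or `scripts/acceptance.py`.

## Psychometric model and QUEST

Detection is log-Weibull in log10 intensity with shape (slope 3.5,
guess 0.01, lapse 0.01).  With these constants the curve's own
threshold parameter T is the ~63% point; the 75% point lies 0.0423
log10 units above T (closed form).  All public interfaces speak linear
mA; log10 bookkeeping is internal.

The QUEST posterior is parameterised directly over the 75%-detection
intensity (the quantity the procedure is meant to deliver), i.e. each
grid value *t* indexes a candidate curve whose 75% point is *t*.  The
prior is Gaussian on the log10 grid, centred at the method-of-limits
estimate with SD 0.5 log10 units, spanning ±3 SD over 401 points —
wide enough that a coarse start off by a factor of three costs nothing.
Stimuli are placed at the posterior mean (quantile placement is a
config option).  Two independent posteriors are administered in strict
alternation, 40 trials each, and combined by averaging their posterior
means (a pooled product-posterior combination is available).  Across
200 simulated log-Weibull observers the true detection probability at
the final estimate averages ~75%, which is the procedure's calibration
check.

The method of limits presents single stimuli, ascending until a
detection, then descending until a miss, and so on; the coarse
threshold is the mean of the first five detection intensities.  The
step is additive by default (`step_mode="multiplicative"` switches to
proportional steps); with a 0.01 mA step the estimate lands within one
step of a deterministic observer's true threshold.

Staircase convergence is the first trial index from which the mean
absolute between-staircase intensity difference (linear mA) over all
remaining trials falls below 5% of the estimated threshold.

Pinprick thresholds are the geometric mean of the three detected and
two undetected forces; the dispersion is the SD of the log forces,
which back-transforms to a multiplicative factor.

## Task schedule

12 blocks × 30 trials of four types named by expected detection rate
(T75, T50, T25, T0).  Exact per-block counts are a fixed default table
(fully config-overridable) with three contingency-rich acquisition
blocks (21 T75 each) and a non-linear extinction profile ending at 21
cue-only trials in block 12; T75 counts are non-increasing and T0
counts non-decreasing across blocks, and every block sums to 30.  The
visual cue is present on every trial, including zero-intensity trials.
Trial order is a seeded permutation within each block.  Breaks (after
blocks 3, 6, 9) and the 4 s response window are metadata only; no
timing is simulated.

## Perceptual and response model

The 3-level binary HGF uses the standard one-step variational updates
(precision-weighted prediction errors, original non-mean-field
variant; the mean-field variant is out of scope here).  Defaults:
κ = 1, ω = −4.2, ϑ = 0.005, initial states μ₂ = 0, σ₂ = 0.1, μ₃ = 1,
σ₃ = 1.  No drift parameters.  A non-positive level-3 precision raises
an explicit divergence error carrying the trial index; there is no
silent NaN path, and the fitter treats divergence as −∞ likelihood.

The filter is driven by the *fused* level-1 belief rather than the raw
binary outcome: the observation model defines perception itself as
inference, so what the learner consolidates is what it perceived.  At
ν = 0 the fused belief equals the observation and the standard
input-driven filter is recovered.

The "observation" of the fusion rule is the expected detection
probability of the administered intensity under the subject's
psychometric curve — both fusion arguments must live on the
probability scale for the rule to read as a posterior.  Zero-intensity
trials map to observation 0 by default (no sensory evidence); mapping
them to the curve's guess-rate floor is a config switch, as is a raw
normalised-intensity observation.

The decision rule is the logistic of β(V₁ − V₀) with V₁ = belief and
V₀ = 1 − belief.  β → 0 gives chance responding (the session
log-likelihood limit 360·log ½ is tested); large β approaches a hard
threshold at belief 0.5.

A note on ν conventions: in this package ν > 1 always means the prior
outweighs the observation (the fusion coefficient on the observation
is 1/(1+ν) < ½).  Descriptions of this parameter elsewhere are not
always internally consistent; every painlearn interface, label and
classification follows the fusion equation itself.

## Inversion

Free parameters (ν, β, ω) are estimated as MAP in transformed space:
log ν ~ N(0, 1), log β ~ N(log 5, 1), ω ~ N(−4.2, 16).  The ω prior
centre is the value at which the filter converges reliably across
subjects; its variance is a weak, toolbox-style choice.  κ and ϑ stay
fixed by default (freeing them is a prior-spec change away) because ω
and ν absorb the behaviourally identifiable variance in this task; ω
itself is only weakly identified at a single session, which the wide
prior acknowledges.

Optimisation is seeded multistart BFGS (default 8 starts: prior means
plus prior draws), rejecting candidates whose filter diverges.  LME is
the Laplace approximation log p(y,θ̂) + (d/2)log 2π − ½ log det H with
a central-difference Hessian; a non-positive-definite Hessian yields
LME = None with AIC still reported.  On a 1-D Gaussian log-joint the
Laplace value is exact, which the suite verifies; on 20-trial sessions
the MAP mode agrees with an exhaustive 101 × 101 grid search.

## Model comparison

"HGF without ν" is the exact nested reduction at ν = 0 (free: β, ω);
its likelihood is bitwise-identical to the full model evaluated at
ν = 0.  The Rescorla–Wagner baseline uses the delta rule
v ← v + α(o − v) from v₀ = 0.5 (maximal uncertainty), with the
pre-update v as the belief in the shared decision rule (free: α on a
logit scale, β).  Fixed-effects BMS sums LMEs; random-effects BMS runs
the variational Dirichlet scheme (uniform Dirichlet(1) prior) with
seeded Monte-Carlo exceedance probabilities.  On simulated data each
generator model wins its own sessions by LME in the majority of 20
replicates per generator.  The simulation check reports per-block
detection-rate curves (mean ± SD over replicates) and the trial-wise
response-match rate against an observed session.

## Synthetic cohort

Defaults: log ν ~ N(log 0.6, 1) — a calibration putting ~30% of agents
above ν = 1 (Φ-tail ≈ 0.305) with the majority sensory-weighted, not
an inference; log β ~ N(log 8, 0.25); ω a point mass at −4.2; log10
thresholds ~ N(−1.05, 0.25), i.e. a median ~0.09 mA with positive,
right-skewed spread on the linear scale.  Each agent gets its own
schedule permutation and response stream from named seed substreams,
recorded in a manifest that fitting code never reads.

What the generator emulates: threshold-level detection with cue
conditioning, individual psychometric curves, decision noise, and
prior-driven false alarms on cue-only trials (their rate
rank-correlates with the generating ν across a cohort).  What it does
not: reaction times, habituation/sensitization drift, lapses of
attention beyond the fixed lapse rate, demographic structure, or any
within-session change in the psychometric curve.  Passing recovery
tests therefore show identifiability under the model's own
assumptions, not robustness to their violation.

Recovery at the default cohort (50 agents, 360 trials, 4 multistarts
per fit — a deliberate cohort-scale economy; single-session fits
default to 8) achieves Spearman ρ ≥ 0.7 between true and recovered
log ν.  Recovered ν shows mild upward bias at small true ν, where the
likelihood flattens (the prior pulls log ν toward 0).

## QST measures

PDT: pressure at the first VAS ≥ 1 cm crossing, linearly interpolated
between samples (ramps are discrete; 1 kPa/s nominal).  PTT: pressure
at the stop event, or the 100 kPa cap as a conservative estimate; a
trace with neither is an error, never a guess.  TSP: ratings are
normalised by subtracting the first rating, and the effect ratio is
mean(pulses 8–10)/mean(pulses 1–3) on the normalised series — so pulse
1 contributes 0 to the early mean, and adding a constant to all
ratings changes nothing.  The raw-series ratio is a config switch
since the normalisation/ratio interaction is a convention.  CPM:
conditioned PTT minus baseline PTT, positive = inhibitory.

## Numerical choices and limitations

- Likelihood recursions run in plain scalar arithmetic (≈0.1 ms per
  360-trial session), making grid oracles and multistart fits cheap;
  array trajectories are built once per public call.
- Bernoulli log-probabilities use softplus forms; the logistic is
  branch-stable for |z| up to overflow.
- QUEST grid likelihoods are clipped at 1e−300 before logs; posterior
  mass conservation is tested at 1e−10.
- Problem sizes used by the validation suite — 200 QUEST replicates,
  10,000-trial rate checks, 500-agent calibration, 50-agent recovery,
  20 replicates per generator for identification — were chosen as the
  smallest sizes at which Monte-Carlo error is comfortably below the
  effects being checked.
- Group-level covariate analyses (regressions of ν on QST measures,
  demographic effects) are out of scope; the toolkit stops at
  per-subject fits and group-level model selection.
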