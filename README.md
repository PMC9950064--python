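# painlearn

Tools for studying how prior expectations shape the perception of
near-threshold nociceptive (pricking) stimuli.  The package implements
the complete computational pipeline of a cue-conditioning detection
experiment — adaptive threshold estimation, task-schedule generation,
hierarchical Bayesian modelling of trial-wise perception, model fitting
and comparison — validated end to end on simulated agents, plus the
standard cuff-algometry outcome measures (PDT, PTT, TSP, CPM) used to
characterise central pain processing.

It is aimed at computational-psychophysics researchers who want to
simulate, fit or power-analyse this class of paradigm without hardware.

## The model

Detection probability of an electrical stimulus at log10 intensity *x*
follows a log-Weibull psychometric function

    p(x) = δγ + (1 − δ)(1 − (1 − γ) e^(−10^{β_w (x − T)}))

with slope β_w = 3.5, guess rate γ = 0.01 and lapse rate δ = 0.01.  The
threshold is estimated by a dual interleaved 40-trial QUEST procedure (a
grid posterior over the 75%-detection intensity), started from a
method-of-limits coarse estimate.  Inverting the fitted curve yields the
stimulus intensities detected with 75/50/25% probability that populate a
12-block × 30-trial conditioning/extinction schedule (suprathreshold,
cue-paired trials dominate early blocks; cue-only zero-intensity trials
dominate late blocks).

Trial-wise perception is modelled with a 3-level binary hierarchical
Gaussian filter (HGF).  Level 2 tracks the cue–stimulus contingency
*x₂*, level 3 its volatility *x₃*; the trial-start prior of a stimulus
is s(μ₂).  Perception fuses this prior with the sensory observation
*o* ∈ [0, 1] (the expected detection probability of the administered
intensity):

    belief = prior + (o − prior) / (1 + ν)

so ν > 1 means the prior outweighs the sensory evidence, ν < 1 the
reverse, and ν = 1 exact balance.  Responses follow a logistic decision
rule P(yes) = σ(β(2·belief − 1)), and the fused belief drives the HGF
update, so learning itself depends on ν.  Per-session (ν, β, ω) are
estimated by multistart MAP in transformed space with Laplace log model
evidence (LME) and AIC; baselines (the nested ν = 0 model and a
Rescorla–Wagner learner) are compared by fixed- and random-effects
Bayesian model selection.

## Worked example

Simulate a threshold run against a stochastic observer whose true
75%-detection point is 0.09 mA:

```sh
$ painlearn quest-sim --seed 1 --out out/quest
{
  "coarse_start_mA": 0.064,
  "final_threshold_mA": 0.09977614928089006,
  "true_detection_prob_at_estimate": 0.7566405413965392,
  "convergence_trial": 40
}
```

The method of limits lands at 0.064 mA; after 2 × 40 QUEST trials the
combined estimate is 0.0998 mA, an intensity the simulated observer
truly detects 75.7% of the time — the procedure's target.  The
staircase traces are written to `out/quest/staircases.csv`.

A parameter-recovery experiment over a small synthetic cohort:

```sh
$ painlearn recover --n-agents 10 --n-starts 4 --seed 1 --out out/recovery.json
recovery over 10 agents: spearman(log nu) = 0.879, rmse(log nu) = 0.495
```

Ten agents with known ν drawn from the default cohort distribution are
simulated through the 360-trial task and refit blind; the rank
correlation of 0.88 between true and recovered log ν shows the weighting
parameter is identifiable from a single session.

The same steps are available as library calls (`run_dual_quest`,
`simulate_agent`, `fit_map`, `recovery_experiment`); see the module
docstrings and `docs/methods.md`.

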