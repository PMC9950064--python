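"""Baseline models and Bayesian model selection.

Three candidate accounts of the behavioural sessions are compared:

- ``hgf_nu``: the full model — HGF prior fused with the observation via
  the nu-weighted rule, logistic decision noise (free: nu, beta, omega);
- ``hgf_no_nu``: the nested reduction at nu = 0, where the fused belief
  collapses onto the observation and perception is purely sensory-driven
  (free: beta, omega);
- ``rescorla_wagner``: a non-Bayesian delta-rule learner whose value v is
  used directly as the belief in the same decision rule (free: alpha,
  beta).

Group-level selection is reported both as fixed effects (summed log model
evidences) and random effects (variational Dirichlet over model
frequencies with Monte-Carlo exceedance probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inversion import (
    MapResult,
    ParamPrior,
    PriorSpec,
    SubjectFit,
    default_priors,
    map_fit_generic,
)
from .psychophysics import PsychometricCurve
from .response_model import (
    ObsParams,
    Session,
    _log_bernoulli,
    _loglik_value,
    observation_sequence,
    simulate_agent,
)
from .task_schedule import TrialSchedule

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "BMSResult",
    "rw_filter",
    "model_loglik",
    "fit_model",
    "bms_fixed",
    "bms_random",
    "simulation_check",
]

MODEL_NAMES = ("hgf_nu", "hgf_no_nu", "rescorla_wagner")


@dataclass(frozen=True)
class ModelSpec:
    """Name and free-parameter list of one candidate model."""

    name: str
    free_params: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")


MODEL_SPECS = {
    "hgf_nu": ModelSpec("hgf_nu", ("nu", "beta", "omega")),
    "hgf_no_nu": ModelSpec("hgf_no_nu", ("beta", "omega")),
    "rescorla_wagner": ModelSpec("rescorla_wagner", ("alpha", "beta")),
}


def rw_filter(alpha: float, observation_sequence, v0: float = 0.5) -> np.ndarray:
    """Rescorla-Wagner value trajectory v <- v + alpha*(obs - v).

    Returns the *predictions*: entry k is the value held before seeing
    observation k (v[0] = v0), so it plays the same role as the HGF's
    trial-start belief.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    obs = np.asarray(observation_sequence, dtype=float)
    if obs.size and (obs.min() < 0 or obs.max() > 1):
        raise ValueError("observations must lie in [0, 1]")
    v = np.empty(obs.size)
    cur = v0
    for k, o in enumerate(obs):
        v[k] = cur
        cur = cur + alpha * (o - cur)
    return v


def _rw_loglik(obs, resp, alpha: float, beta: float) -> float:
    v = rw_filter(alpha, obs)
    return sum(
        _log_bernoulli(r, beta * (2.0 * b - 1.0)) for r, b in zip(resp, v)
    )


def model_loglik(
    model: ModelSpec | str,
    session: Session,
    curve: PsychometricCurve,
    params: dict,
    priors: PriorSpec | None = None,
) -> float:
    """Session log-likelihood under any of the three candidate models.

    ``params`` supplies the model's free parameters by name; ``priors``
    carries the fixed perceptual constants for the HGF variants.
    """
    spec = MODEL_SPECS[model] if isinstance(model, str) else model
    missing = set(spec.free_params) - set(params)
    if missing:
        raise ValueError(f"missing parameters for {spec.name}: {missing}")
    priors = priors or default_priors()
    obs = observation_sequence(session.schedule, curve)
    resp = list(session.responses)
    if spec.name == "rescorla_wagner":
        return _rw_loglik(obs, resp, params["alpha"], params["beta"])
    nu = params["nu"] if spec.name == "hgf_nu" else 0.0
    hgf = priors.hgf_params(params["omega"])
    return _loglik_value(obs, resp, nu, params["beta"], hgf)


def fit_model(
    model: ModelSpec | str,
    session: Session,
    curve: PsychometricCurve,
    priors: PriorSpec | None = None,
    *,
    n_starts: int = 8,
    seed: int | None = None,
) -> MapResult:
    """MAP fit of one candidate model to one session.

    All models share the Gaussian-in-transformed-space prior machinery:
    log nu, log beta, identity omega, logit alpha (alpha ~ logistic of a
    standard normal, i.e. centred on 0.5).
    """
    spec = MODEL_SPECS[model] if isinstance(model, str) else model
    priors = priors or default_priors()
    obs = observation_sequence(session.schedule, curve)
    resp = list(session.responses)

    if spec.name == "rescorla_wagner":
        def loglik_fn(nat: dict) -> float:
            return _rw_loglik(obs, resp, nat["alpha"], nat["beta"])

        free = {"alpha": ParamPrior("logit", 0.0, 1.0), "beta": priors.beta}
    else:
        nu_fixed_zero = spec.name == "hgf_no_nu"

        def loglik_fn(nat: dict) -> float:
            nu = 0.0 if nu_fixed_zero else nat["nu"]
            hgf = priors.hgf_params(nat["omega"])
            return _loglik_value(obs, resp, nu, nat["beta"], hgf)

        free = {"beta": priors.beta, "omega": priors.omega}
        if not nu_fixed_zero:
            free = {"nu": priors.nu, **free}

    return map_fit_generic(loglik_fn, free, n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# group-level Bayesian model selection


@dataclass(frozen=True)
class BMSResult:
    """Random-effects BMS output.

    ``alpha`` is the posterior Dirichlet concentration over model
    frequencies, ``expected_freq`` its mean, and ``exceedance`` the
    Monte-Carlo probability of each model being the most frequent.
    """

    model_names: tuple[str, ...]
    alpha: np.ndarray
    expected_freq: np.ndarray
    exceedance: np.ndarray


def _as_matrix(lme_matrix) -> np.ndarray:
    m = np.asarray(lme_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("lme_matrix must be 2-D (subjects x models)")
    return m


def bms_fixed(lme_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effects BMS: summed LMEs and posterior model probabilities.

    Subjects with any non-finite LME are excluded from the sums (they are
    counted in neither model's evidence).
    """
    m = _as_matrix(lme_matrix)
    ok = np.all(np.isfinite(m), axis=1)
    group = m[ok].sum(axis=0)
    z = group - group.max()
    p = np.exp(z) / np.exp(z).sum()
    return group, p


def bms_random(
    lme_matrix,
    seed: int | None = None,
    *,
    alpha0: float = 1.0,
    n_samples: int = 20_000,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> BMSResult:
    """Random-effects BMS by variational Dirichlet update.

    Iterates the standard scheme: subject-wise model responsibilities
    proportional to exp(LME + digamma(alpha_k) - digamma(sum alpha)),
    Dirichlet concentration alpha = alpha0 + summed responsibilities.
    Exceedance probabilities are estimated by seeded sampling from the
    fitted Dirichlet.
    """
    from scipy.special import digamma

    m = _as_matrix(lme_matrix)
    n_sub, n_mod = m.shape
    if n_sub < 2 or n_mod < 2:
        raise ValueError("random-effects BMS needs >= 2 subjects and models")
    ok = np.all(np.isfinite(m), axis=1)
    m = m[ok]
    if m.shape[0] < 2:
        raise ValueError("fewer than 2 subjects with finite evidences")
    alpha = np.full(n_mod, alpha0, dtype=float)
    for _ in range(max_iter):
        w = m + digamma(alpha) - digamma(alpha.sum())
        w = w - w.max(axis=1, keepdims=True)
        u = np.exp(w)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    exceed = np.bincount(winners, minlength=n_mod) / n_samples
    return BMSResult(
        model_names=MODEL_NAMES[:n_mod] if n_mod <= 3 else tuple(
            f"m{i}" for i in range(n_mod)
        ),
        alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        exceedance=exceed,
    )


# ---------------------------------------------------------------------------
# simulation-based model check


@dataclass(frozen=True)
class SimulationCheck:
    """Agreement between a fitted model's simulations and an observed session."""

    per_block: pd.DataFrame       # block, observed_rate, sim_mean, sim_sd
    match_rate: float             # mean trial-wise response agreement
    n_reps: int


def simulation_check(
    fit: SubjectFit,
    schedule: TrialSchedule,
    curve: PsychometricCurve,
    observed_session: Session,
    seed: int | None = None,
    n_reps: int = 20,
    priors: PriorSpec | None = None,
) -> SimulationCheck:
    """Simulate from fitted parameters and compare with the observed session.

    Reports the per-block detection-rate curve of the simulations (mean
    and SD over replicates) against the observed one, and the mean
    trial-wise response-match rate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    priors = priors or default_priors()
    hgf = priors.hgf_params(fit.omega)
    obs_params = ObsParams(nu=fit.nu, beta_slope=fit.beta)
    rng = np.random.default_rng(seed)
    observed = np.asarray(observed_session.responses)
    blocks = schedule.trials.block.to_numpy()
    block_ids = np.unique(blocks)

    sim_rates = np.empty((n_reps, block_ids.size))
    matches = np.empty(n_reps)
    for r in range(n_reps):
        sess, _ = simulate_agent(
            schedule, curve, hgf, obs_params,
            seed=int(rng.integers(2**31 - 1)),
        )
        resp = np.asarray(sess.responses)
        matches[r] = float(np.mean(resp == observed))
        for j, blk in enumerate(block_ids):
            sim_rates[r, j] = resp[blocks == blk].mean()

    obs_rates = [observed[blocks == blk].mean() for blk in block_ids]
    per_block = pd.DataFrame(
        {
            "block": block_ids,
            "observed_rate": obs_rates,
            "sim_mean": sim_rates.mean(axis=0),
            "sim_sd": sim_rates.std(axis=0),
        }
    )
    return SimulationCheck(
        per_block=per_block,
        match_rate=float(matches.mean()),
        n_reps=n_reps,
    )
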