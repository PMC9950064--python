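"""Observation model: prior/sensory fusion, decision rule, agent simulation.

On every trial the agent holds a prior probability of a stimulus (the
level-1 prediction s(mu2) of the HGF) and receives an observation in
[0, 1] — the expected detection probability of the administered intensity
under the subject's psychometric curve.  These are fused as

    belief = prior + (observation - prior) / (1 + nu)

so that nu > 1 weights the prior more than the observation and nu < 1
weights the observation more; nu = 1 is the equal-weighting midpoint and
nu = 0 the purely sensory-driven limit.  The probability of reporting
"felt" is a logistic function of the value difference between detection
(V1 = belief) and non-detection (V0 = 1 - belief) scaled by the decision
noise beta:

    P(yes) = logistic(beta * (2*belief - 1)).

The fused belief (not the raw stimulus) drives the HGF update, so the
learning trajectory itself depends on nu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import IncompleteSessionError, ModelDivergenceError
from .hgf_core import HGFParams, HGFTrajectory, hgf_filter
from .psychophysics import PsychometricCurve, weibull_detection_prob
from .task_schedule import TrialSchedule

__all__ = [
    "ObsParams",
    "TrialObservation",
    "Session",
    "SessionLikelihood",
    "fuse_belief",
    "response_prob",
    "trial_observation",
    "observation_sequence",
    "simulate_agent",
    "session_loglik",
]


@dataclass(frozen=True)
class ObsParams:
    """Observation-model parameters: prior weight nu and decision slope beta."""

    nu: float
    beta_slope: float

    def __post_init__(self) -> None:
        if self.nu < 0:
            raise ValueError("nu must be non-negative")
        if self.beta_slope <= 0:
            raise ValueError("beta_slope must be positive")


@dataclass(frozen=True)
class TrialObservation:
    """Sensory observation on the probability scale plus its source intensity."""

    value: float
    source_intensity_mA: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("observation value must lie in [0, 1]")


@dataclass(frozen=True)
class Session:
    """A completed task run: schedule plus one binary response per trial."""

    schedule: TrialSchedule
    responses: tuple[int, ...]
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        if len(self.responses) != len(self.schedule):
            raise IncompleteSessionError(
                f"{len(self.schedule)} trials but "
                f"{len(self.responses)} responses"
            )
        if any(r not in (0, 1) for r in self.responses):
            raise IncompleteSessionError("responses must be binary 0/1")


def fuse_belief(prior: float, observation: float, nu: float) -> float:
    """Convex fusion of prior and observation with weight nu on the prior."""
    if not 0.0 <= prior <= 1.0 or not 0.0 <= observation <= 1.0:
        raise ValueError("prior and observation must lie in [0, 1]")
    if nu < 0:
        raise ValueError("nu must be non-negative")
    return prior + (observation - prior) / (1.0 + nu)


def response_prob(belief: float, beta_slope: float) -> float:
    """P(report 'felt') under the logistic decision rule.

    V1 = belief and V0 = 1 - belief, so the decision variable is
    beta * (2*belief - 1).
    """
    if not 0.0 <= belief <= 1.0:
        raise ValueError("belief must lie in [0, 1]")
    z = beta_slope * (2.0 * belief - 1.0)
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def trial_observation(
    intensity_mA: float,
    curve: PsychometricCurve,
    *,
    clamp_zero: bool = True,
) -> TrialObservation:
    """Map a stimulus intensity to the [0, 1] observation scale.

    Positive intensities map through the psychometric curve (expected
    detection probability); zero intensity maps to the curve floor, or to
    exactly 0 when ``clamp_zero`` (the default) — a cue-only trial carries
    no sensory evidence.
    """
    if intensity_mA < 0:
        raise ValueError("intensity must be non-negative")
    if intensity_mA == 0:
        value = 0.0 if clamp_zero else curve.floor
    else:
        value = weibull_detection_prob(curve, math.log10(intensity_mA))
    return TrialObservation(value=value, source_intensity_mA=intensity_mA)


def observation_sequence(
    schedule: TrialSchedule,
    curve: PsychometricCurve,
    *,
    clamp_zero: bool = True,
) -> np.ndarray:
    """Observation values for every trial of a schedule, in order."""
    return np.array(
        [
            trial_observation(x, curve, clamp_zero=clamp_zero).value
            for x in schedule.trials.intensity_mA
        ]
    )


# ---------------------------------------------------------------------------
# fast scalar core (shared by simulation and likelihood)


def _log_bernoulli(resp: int, z: float) -> float:
    # log P(resp) with P(yes) = logistic(z), stable for large |z|
    t = z if resp else -z
    if t > 35.0:
        return -math.exp(-t)
    if t < -35.0:
        return t
    return -math.log1p(math.exp(-t))


def _run_core(obs, resp, nu, beta, p: HGFParams, rng=None):
    """Shared belief/likelihood recursion in plain floats.

    If ``rng`` is given, responses are sampled (simulation) and ``resp``
    is ignored; otherwise ``resp`` is scored.  Returns (loglik, beliefs,
    responses, diverged_at) where diverged_at is None or the 0-based trial
    index at which the level-3 precision failed.
    """
    kappa, omega, theta = p.kappa, p.omega, p.theta
    mu2, s2 = p.init_mu2, p.init_sigma2
    mu3, s3 = p.init_mu3, p.init_sigma3
    inv1nu = 1.0 / (1.0 + nu)
    loglik = 0.0
    beliefs = []
    responses = []
    for k, o in enumerate(obs):
        # predict
        if mu2 >= 0:
            muhat1 = 1.0 / (1.0 + math.exp(-mu2))
        else:
            e = math.exp(mu2)
            muhat1 = e / (1.0 + e)
        b = muhat1 + (o - muhat1) * inv1nu
        z = beta * (2.0 * b - 1.0)
        if rng is not None:
            r = int(rng.random() < (1.0 / (1.0 + math.exp(-z)) if z >= 0
                                    else math.exp(z) / (1.0 + math.exp(z))))
        else:
            r = resp[k]
        loglik += _log_bernoulli(r, z)
        beliefs.append(b)
        responses.append(r)
        # update
        v2 = math.exp(kappa * mu3 + omega)
        pihat2 = 1.0 / (s2 + v2)
        pihat3 = 1.0 / (s3 + theta)
        delta1 = b - muhat1
        pi2 = pihat2 + muhat1 * (1.0 - muhat1)
        mu2_new = mu2 + delta1 / pi2
        delta2 = (1.0 / pi2 + (mu2_new - mu2) ** 2) * pihat2 - 1.0
        w2 = v2 / (s2 + v2)
        r2 = (v2 - s2) / (v2 + s2)
        pi3 = pihat3 + 0.5 * kappa * kappa * w2 * (w2 + r2 * delta2)
        if pi3 <= 0.0 or not math.isfinite(pi3):
            return -math.inf, beliefs, responses, k
        mu3 = mu3 + 0.5 * kappa * (w2 / pi3) * delta2
        mu2, s2, s3 = mu2_new, 1.0 / pi2, 1.0 / pi3
    return loglik, beliefs, responses, None


@dataclass(frozen=True)
class SessionLikelihood:
    """Log-likelihood of a session with its belief trajectory."""

    loglik: float
    trajectory: HGFTrajectory
    diverged: bool = False
    diverged_at: int | None = None


def simulate_agent(
    schedule: TrialSchedule,
    curve: PsychometricCurve,
    hgf_params: HGFParams,
    obs_params: ObsParams,
    seed: int | None = None,
    *,
    subject_id: str = "sim",
    clamp_zero: bool = True,
) -> tuple[Session, HGFTrajectory]:
    """Simulate one agent through a schedule.

    Per trial: predict (prior = s(mu2)), fuse with the observation, draw a
    Bernoulli response from the decision rule, and update the filter with
    the fused belief.  Reproducible under a fixed seed.
    """
    obs = observation_sequence(schedule, curve, clamp_zero=clamp_zero)
    rng = np.random.default_rng(seed)
    loglik, beliefs, responses, div = _run_core(
        obs, None, obs_params.nu, obs_params.beta_slope, hgf_params, rng=rng
    )
    if div is not None:
        raise ModelDivergenceError(
            "simulation diverged", trial=div
        )
    traj = hgf_filter(hgf_params, beliefs)
    session = Session(
        schedule=schedule, responses=tuple(responses), subject_id=subject_id
    )
    return session, traj


def session_loglik(
    session: Session,
    curve: PsychometricCurve,
    hgf_params: HGFParams,
    obs_params: ObsParams,
    *,
    clamp_zero: bool = True,
) -> SessionLikelihood:
    """Log-likelihood of observed responses under the full model.

    A filter divergence yields loglik = -inf with the ``diverged`` flag
    set and the trajectory truncated at the failing trial.
    """
    obs = observation_sequence(session.schedule, curve, clamp_zero=clamp_zero)
    loglik, beliefs, _, div = _run_core(
        obs, session.responses, obs_params.nu, obs_params.beta_slope,
        hgf_params,
    )
    traj = hgf_filter(hgf_params, beliefs[: div] if div is not None else beliefs)
    return SessionLikelihood(
        loglik=loglik,
        trajectory=traj,
        diverged=div is not None,
        diverged_at=div,
    )


def _loglik_value(obs, resp, nu, beta, hgf_params) -> float:
    """Fast likelihood-only path used by the fitters."""
    loglik, _, _, _ = _run_core(obs, resp, nu, beta, hgf_params)
    return loglik
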