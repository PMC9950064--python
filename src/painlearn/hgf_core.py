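"""Three-level binary Hierarchical Gaussian Filter (HGF).

Generative model: the probability of a binary outcome x1 is the logistic
sigmoid of a latent tendency x2 (the cue-stimulus contingency), which
performs a Gaussian random walk whose step variance exp(kappa*x3 + omega)
is controlled by a volatility state x3; x3 itself random-walks with
constant variance theta.  Variational inversion yields closed-form,
trial-by-trial update equations in which each level is corrected by the
precision-weighted prediction error from the level below.

The filter here is driven by a *level-1 belief* b in [0, 1] rather than a
raw binary input: in the perceptual model of this package, b is the fused
posterior probability of a stimulus produced by the response model, so
that perception itself (not just learning) is inferential.  Feeding the
raw binary outcome as b recovers the standard input-driven binary HGF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ModelDivergenceError

__all__ = [
    "HGFParams",
    "HGFState",
    "HGFTrajectory",
    "sigmoid",
    "hgf_predict",
    "hgf_update",
    "hgf_filter",
]


@dataclass(frozen=True)
class HGFParams:
    """Perceptual-model parameters.

    kappa >= 0 couples the volatility level to the level-2 learning rate;
    omega is the tonic log-volatility of level 2; theta > 0 is the
    constant volatility of level 3.  Initial means/variances of levels 2
    and 3 follow the customary toolbox defaults.
    """

    kappa: float = 1.0
    omega: float = -4.2
    theta: float = 0.005
    init_mu2: float = 0.0
    init_sigma2: float = 0.1
    init_mu3: float = 1.0
    init_sigma3: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.init_sigma2 <= 0 or self.init_sigma3 <= 0:
            raise ValueError("initial variances must be positive")

    def initial_state(self) -> "HGFState":
        return HGFState(
            mu2=self.init_mu2,
            sigma2=self.init_sigma2,
            mu3=self.init_mu3,
            sigma3=self.init_sigma3,
        )


@dataclass(frozen=True)
class HGFState:
    """Posterior means and variances of levels 2 and 3."""

    mu2: float
    sigma2: float
    mu3: float
    sigma3: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0 or self.sigma3 <= 0:
            raise ValueError("variances must be positive")


def sigmoid(x: float) -> float:
    """Numerically stable logistic sigmoid 1/(1+exp(-x))."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def hgf_predict(
    state: HGFState, params: HGFParams
) -> tuple[float, float, float]:
    """Trial-start predictions: (muhat1, pihat2, pihat3).

    muhat1 = s(mu2) is the predicted outcome probability; pihat2 and
    pihat3 are the precisions of the level-2 and level-3 predictions after
    adding the random-walk step variances.
    """
    muhat1 = sigmoid(state.mu2)
    v2 = math.exp(params.kappa * state.mu3 + params.omega)
    pihat2 = 1.0 / (state.sigma2 + v2)
    pihat3 = 1.0 / (state.sigma3 + params.theta)
    return muhat1, pihat2, pihat3


def hgf_update(
    state: HGFState, params: HGFParams, b: float
) -> tuple[HGFState, float, float]:
    """One-step variational update driven by the level-1 belief b.

    Returns (new_state, delta1, delta2) where delta1 = b - muhat1 is the
    level-1 prediction error and delta2 the volatility prediction error
    passed up to level 3.  Raises :class:`ModelDivergenceError` if the
    level-3 precision comes out non-positive (the standard failure mode of
    this update for inconsistent kappa/omega/theta settings).
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError("level-1 belief must lie in [0, 1]")
    muhat1, pihat2, pihat3 = hgf_predict(state, params)
    v2 = math.exp(params.kappa * state.mu3 + params.omega)

    # level 2
    delta1 = b - muhat1
    pi2 = pihat2 + muhat1 * (1.0 - muhat1)
    mu2_new = state.mu2 + delta1 / pi2

    # volatility prediction error of level 2, passed to level 3
    delta2 = (1.0 / pi2 + (mu2_new - state.mu2) ** 2) * pihat2 - 1.0

    # level 3
    w2 = v2 / (state.sigma2 + v2)
    r2 = (v2 - state.sigma2) / (v2 + state.sigma2)
    pi3 = pihat3 + 0.5 * params.kappa**2 * w2 * (w2 + r2 * delta2)
    if pi3 <= 0.0 or not math.isfinite(pi3):
        raise ModelDivergenceError(
            f"level-3 precision non-positive (pi3={pi3:.4g})"
        )
    mu3_new = state.mu3 + 0.5 * params.kappa * (w2 / pi3) * delta2

    new_state = HGFState(
        mu2=mu2_new, sigma2=1.0 / pi2, mu3=mu3_new, sigma3=1.0 / pi3
    )
    return new_state, delta1, delta2


@dataclass(frozen=True)
class HGFTrajectory:
    """Per-trial beliefs, precisions and prediction errors.

    Arrays are aligned so that row k holds the trial-k prediction
    (``muhat1``), the belief that drove the update (``belief``), the
    post-update level-2/3 posteriors and both prediction errors.
    """

    muhat1: np.ndarray
    belief: np.ndarray
    mu2: np.ndarray
    sigma2: np.ndarray
    mu3: np.ndarray
    sigma3: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray

    def __len__(self) -> int:
        return len(self.muhat1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "muhat1": self.muhat1,
                "belief": self.belief,
                "mu2": self.mu2,
                "sigma2": self.sigma2,
                "mu3": self.mu3,
                "sigma3": self.sigma3,
                "delta1": self.delta1,
                "delta2": self.delta2,
            }
        )


def hgf_filter(
    params: HGFParams, belief_sequence: Sequence[float]
) -> HGFTrajectory:
    """Run the filter over a sequence of level-1 beliefs.

    Equivalent to iterating :func:`hgf_predict` / :func:`hgf_update` from
    the parameter-specified initial state.  A divergence is re-raised with
    the offending trial index attached.
    """
    n = len(belief_sequence)
    cols = {k: np.empty(n) for k in
            ("muhat1", "belief", "mu2", "sigma2", "mu3", "sigma3",
             "delta1", "delta2")}
    state = params.initial_state()
    for k, b in enumerate(belief_sequence):
        muhat1, _, _ = hgf_predict(state, params)
        try:
            state, d1, d2 = hgf_update(state, params, float(b))
        except ModelDivergenceError as err:
            raise ModelDivergenceError(str(err), trial=k) from err
        cols["muhat1"][k] = muhat1
        cols["belief"][k] = b
        cols["mu2"][k] = state.mu2
        cols["sigma2"][k] = state.sigma2
        cols["mu3"][k] = state.mu3
        cols["sigma3"][k] = state.sigma3
        cols["delta1"][k] = d1
        cols["delta2"][k] = d2
    return HGFTrajectory(**cols)
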