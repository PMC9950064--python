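"""Log-Weibull psychometrics and QUEST adaptive threshold estimation.

The perceptual threshold for electrical (pricking) stimulation is estimated
in three stages that this module implements end to end:

1. a coarse *method of limits* with alternating ascending/descending runs,
   stopped after five detection events, providing a starting value;
2. a Bayesian adaptive (QUEST) procedure with two interleaved 40-trial
   staircases, each maintaining a grid posterior over the intensity at
   which detection probability equals a target level (75% by default);
3. a log-Weibull psychometric curve anchored at the QUEST estimate, from
   which the stimulus intensities for any detection probability are
   derived in closed form.

Intensities are bookkept internally in log10 mA (the natural scale of the
log-Weibull and of the QUEST posterior); every public interface takes and
returns linear mA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np

from .errors import (
    InvalidMeasurementError,
    NoDetectionError,
    UnreachableProbabilityError,
)

__all__ = [
    "PsychometricCurve",
    "QuestShape",
    "QuestPosterior",
    "StaircasePair",
    "PinprickMeasurement",
    "DEFAULT_QUEST_SHAPE",
    "weibull_detection_prob",
    "invert_weibull",
    "target_offset",
    "curve_from_quest",
    "method_of_limits",
    "quest_update",
    "quest_next",
    "run_dual_quest",
    "staircase_convergence",
    "pinprick_threshold",
    "make_weibull_observer",
    "make_step_observer",
]


@dataclass(frozen=True)
class PsychometricCurve:
    """Log-Weibull detection model.

    ``threshold_T`` is the log10 intensity (log10 mA) at which the Weibull
    exponent equals one; with the default shape the detection probability
    there is ~0.6295, not 50%.  ``slope_beta_w`` controls steepness,
    ``guess_gamma_w`` the false-alarm floor and ``lapse_delta_w`` the lapse
    rate that caps the ceiling at ``1 - lapse_delta_w + lapse_delta_w *
    guess_gamma_w``.
    """

    threshold_T: float
    slope_beta_w: float = 3.5
    guess_gamma_w: float = 0.01
    lapse_delta_w: float = 0.01

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold_T):
            raise ValueError("threshold_T must be finite")
        if self.slope_beta_w <= 0:
            raise ValueError("slope_beta_w must be positive")
        if not 0 <= self.guess_gamma_w < 1:
            raise ValueError("guess_gamma_w must lie in [0, 1)")
        if not 0 <= self.lapse_delta_w < 1:
            raise ValueError("lapse_delta_w must lie in [0, 1)")

    @property
    def floor(self) -> float:
        """Detection probability as intensity -> 0 (the guess rate)."""
        g, d = self.guess_gamma_w, self.lapse_delta_w
        return d * g + (1 - d) * g

    @property
    def ceiling(self) -> float:
        """Detection probability as intensity -> infinity."""
        g, d = self.guess_gamma_w, self.lapse_delta_w
        return d * g + (1 - d)


class QuestShape(NamedTuple):
    """Shape constants of the QUEST likelihood and its target level.

    ``p_target`` defines which percent point of the psychometric function
    the posterior grid parameterises: a grid value t means "the log10
    intensity detected with probability ``p_target``".
    """

    slope: float = 3.5
    guess: float = 0.01
    lapse: float = 0.01
    p_target: float = 0.75


DEFAULT_QUEST_SHAPE = QuestShape()


def weibull_detection_prob(curve: PsychometricCurve, x):
    """Detection probability at log10 intensity ``x``.

    Implements the standard QUEST log-Weibull

    ``p(x) = d*g + (1 - d) * (1 - (1 - g) * exp(-10**(b*(x - T))))``

    with slope ``b``, guess rate ``g``, lapse rate ``d`` and threshold
    ``T``.  Accepts scalars or numpy arrays; non-finite scalar input is
    rejected.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("intensity must be finite")
    b, T = curve.slope_beta_w, curve.threshold_T
    g, d = curve.guess_gamma_w, curve.lapse_delta_w
    # exponent can overflow for extreme x; clip in log-space first
    expo = np.clip(b * (x - T), -700.0, 300.0)
    p = d * g + (1 - d) * (1 - (1 - g) * np.exp(-np.power(10.0, expo)))
    return float(p) if p.ndim == 0 else p


def invert_weibull(curve: PsychometricCurve, p_target: float) -> float:
    """Log10 intensity at which the curve reaches ``p_target``.

    Closed-form inverse of :func:`weibull_detection_prob`; ``p_target``
    must lie strictly between the curve's floor and ceiling.
    """
    if not (curve.floor < p_target < curve.ceiling):
        raise UnreachableProbabilityError(
            f"p_target={p_target} outside attainable range "
            f"({curve.floor:.6g}, {curve.ceiling:.6g})"
        )
    g, d = curve.guess_gamma_w, curve.lapse_delta_w
    q = (1 - (p_target - d * g) / (1 - d)) / (1 - g)
    return curve.threshold_T + math.log10(-math.log(q)) / curve.slope_beta_w


def target_offset(shape: QuestShape = DEFAULT_QUEST_SHAPE) -> float:
    """Log10 distance from the Weibull threshold T to the ``p_target`` point."""
    ref = PsychometricCurve(0.0, shape.slope, shape.guess, shape.lapse)
    return invert_weibull(ref, shape.p_target)


def curve_from_quest(
    estimate_mA: float, shape: QuestShape = DEFAULT_QUEST_SHAPE
) -> PsychometricCurve:
    """Psychometric curve whose ``p_target`` point sits at the QUEST estimate.

    The QUEST posterior parameterises the intensity detected with
    probability ``shape.p_target``; the Weibull threshold parameter is that
    estimate shifted down by the fixed shape offset.
    """
    if estimate_mA <= 0:
        raise ValueError("QUEST estimate must be a positive intensity in mA")
    T = math.log10(estimate_mA) - target_offset(shape)
    return PsychometricCurve(T, shape.slope, shape.guess, shape.lapse)


# ---------------------------------------------------------------------------
# method of limits


def method_of_limits(
    observer: Callable[[float, np.random.Generator], int],
    start: float,
    step: float,
    seed: int | None = None,
    *,
    n_detections: int = 5,
    cap: float = 10.0,
    step_mode: str = "additive",
) -> float:
    """Coarse threshold by alternating ascending/descending runs.

    Stimuli are presented one at a time starting from ``start`` (linear
    mA), moving upward until a detection, then downward until a miss, and
    so on.  Each detection event records the administered intensity; the
    procedure stops after ``n_detections`` detections and returns their
    arithmetic mean (linear mA).

    ``step_mode`` selects additive (``x + step``) or multiplicative
    (``x * (1 + step)``) increments.  Raises :class:`NoDetectionError` if
    the ascending track exceeds ``cap`` without any detection.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if start <= 0:
        raise ValueError("start intensity must be positive")
    rng = np.random.default_rng(seed)
    floor = min(start, step) if step_mode == "additive" else start * 1e-3

    def up(x: float) -> float:
        return x + step if step_mode == "additive" else x * (1 + step)

    def down(x: float) -> float:
        nxt = x - step if step_mode == "additive" else x / (1 + step)
        return max(nxt, floor)

    detections: list[float] = []
    x = start
    while len(detections) < n_detections:
        if x > cap:
            raise NoDetectionError(
                f"no detection below the {cap} mA cap after "
                f"{len(detections)} detections"
            )
        if observer(x, rng):
            detections.append(x)
            x = down(x)  # flip to a descending run
        else:
            x = up(x)
    return float(np.mean(detections))


# ---------------------------------------------------------------------------
# QUEST


@dataclass
class QuestPosterior:
    """Grid posterior over the target-probability log10 intensity.

    ``grid`` is strictly increasing; ``log_density`` holds the normalised
    log posterior mass per grid point.  ``trial_history`` records the
    administered (log10 intensity, response) pairs in order.
    """

    grid: np.ndarray
    log_density: np.ndarray
    trial_history: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.log_density = np.asarray(self.log_density, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("grid must be a 1-D array with >= 2 points")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.log_density.shape != self.grid.shape:
            raise ValueError("log_density must match grid shape")
        self._normalize()

    def _normalize(self) -> None:
        m = np.max(self.log_density)
        self.log_density = self.log_density - (
            m + np.log(np.sum(np.exp(self.log_density - m)))
        )

    @property
    def density(self) -> np.ndarray:
        return np.exp(self.log_density)

    @property
    def mean(self) -> float:
        """Posterior mean of the target-probability log10 intensity."""
        return float(np.sum(self.grid * self.density))

    def quantile(self, q: float) -> float:
        cdf = np.cumsum(self.density)
        return float(np.interp(q, cdf, self.grid))

    @classmethod
    def from_prior(
        cls,
        mean: float,
        sd: float = 0.5,
        *,
        n_points: int = 401,
        span_sd: float = 3.0,
    ) -> "QuestPosterior":
        """Gaussian prior centred at ``mean`` (log10 mA) with width ``sd``."""
        if sd <= 0:
            raise ValueError("prior sd must be positive")
        grid = np.linspace(mean - span_sd * sd, mean + span_sd * sd, n_points)
        logd = -0.5 * ((grid - mean) / sd) ** 2
        return cls(grid=grid, log_density=logd)


def _grid_likelihood(
    grid: np.ndarray, x: float, shape: QuestShape
) -> np.ndarray:
    """P(yes | target point = grid, stimulus at log10 intensity x)."""
    offset = target_offset(shape)
    curve = PsychometricCurve(0.0, shape.slope, shape.guess, shape.lapse)
    # threshold parameter of each candidate curve is grid - offset
    return weibull_detection_prob(curve, x - (grid - offset))


def quest_update(
    post: QuestPosterior,
    x: float,
    response: int,
    shape: QuestShape = DEFAULT_QUEST_SHAPE,
) -> QuestPosterior:
    """One Bayesian update of the threshold posterior.

    ``x`` is the administered log10 intensity and ``response`` the binary
    detection report.  Returns a new posterior; the input is not mutated.
    """
    if response not in (0, 1):
        raise ValueError("response must be 0 or 1")
    p_yes = _grid_likelihood(post.grid, x, shape)
    p_yes = np.clip(p_yes, 1e-300, 1.0 - 1e-16)
    loglik = np.log(p_yes) if response else np.log1p(-p_yes)
    return QuestPosterior(
        grid=post.grid.copy(),
        log_density=post.log_density + loglik,
        trial_history=post.trial_history + [(float(x), int(response))],
    )


def quest_next(post: QuestPosterior, rule: str = "mean", q: float = 0.5) -> float:
    """Placement of the next stimulus (log10 intensity).

    The default rule places at the posterior mean of the target point;
    ``rule="quantile"`` places at the posterior quantile ``q``.
    """
    if rule == "mean":
        return post.mean
    if rule == "quantile":
        return post.quantile(q)
    raise ValueError(f"unknown placement rule {rule!r}")


@dataclass(frozen=True)
class StaircasePair:
    """Two interleaved QUEST staircases and their combined estimate.

    ``staircase_a``/``staircase_b`` hold the administered intensities in
    linear mA, 40 per staircase, in within-staircase order; presentation
    strictly alternated a, b, a, b, ...  ``final_threshold_mA`` is the
    combined threshold estimate on the linear scale.
    """

    staircase_a: tuple[float, ...]
    staircase_b: tuple[float, ...]
    final_threshold_mA: float

    def __post_init__(self) -> None:
        if len(self.staircase_a) != len(self.staircase_b):
            raise ValueError("staircases must have equal length")


def run_dual_quest(
    observer: Callable[[float, np.random.Generator], int],
    coarse_start_mA: float,
    seed: int | None = None,
    *,
    n_trials: int = 40,
    prior_sd: float = 0.5,
    n_points: int = 401,
    shape: QuestShape = DEFAULT_QUEST_SHAPE,
    placement: str = "mean",
    combine: str = "mean",
) -> tuple[StaircasePair, QuestPosterior, QuestPosterior]:
    """Dual interleaved QUEST staircases from a coarse starting intensity.

    Two independent posteriors are initialised from the same Gaussian prior
    centred at ``log10(coarse_start_mA)``; stimuli are administered in
    strict alternation (a, b, a, b, ...), each staircase placing at its own
    posterior (rule ``placement``) and updating only on its own trials.
    ``combine="mean"`` averages the two posterior means in log10 space;
    ``combine="pooled"`` takes the mean of the pooled (product) posterior.

    Returns the staircase pair (linear mA) and the two final posteriors.
    """
    if coarse_start_mA <= 0:
        raise ValueError("coarse start must be positive (linear mA)")
    rng = np.random.default_rng(seed)
    start_log = math.log10(coarse_start_mA)
    posts = [
        QuestPosterior.from_prior(start_log, prior_sd, n_points=n_points)
        for _ in range(2)
    ]
    traces: list[list[float]] = [[], []]
    for _ in range(n_trials):
        for s in range(2):  # strict alternation a, b
            x = quest_next(posts[s], rule=placement)
            r = int(observer(10.0**x, rng))
            posts[s] = quest_update(posts[s], x, r, shape)
            traces[s].append(10.0**x)
    if combine == "mean":
        final_log = 0.5 * (posts[0].mean + posts[1].mean)
    elif combine == "pooled":
        pooled = QuestPosterior(
            grid=posts[0].grid.copy(),
            log_density=posts[0].log_density + posts[1].log_density,
        )
        final_log = pooled.mean
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    pair = StaircasePair(
        staircase_a=tuple(traces[0]),
        staircase_b=tuple(traces[1]),
        final_threshold_mA=10.0**final_log,
    )
    return pair, posts[0], posts[1]


def staircase_convergence(
    pair: StaircasePair,
    est_threshold_mA: float,
    frac: float = 0.05,
) -> int | None:
    """First trial from which the staircases agree to within a fraction.

    Searches chronologically for the smallest 1-based trial index k such
    that the mean absolute between-staircase intensity difference (linear
    mA) over trials k..n is below ``frac`` times the estimated threshold.
    Returns ``None`` if the criterion is never met.
    """
    if est_threshold_mA <= 0:
        raise ValueError("estimated threshold must be positive")
    a = np.asarray(pair.staircase_a, dtype=float)
    b = np.asarray(pair.staircase_b, dtype=float)
    diffs = np.abs(a - b)
    crit = frac * est_threshold_mA
    # suffix means, scanned from the front
    for k in range(diffs.size):
        if float(np.mean(diffs[k:])) < crit:
            return k + 1
    return None


# ---------------------------------------------------------------------------
# pinprick


@dataclass(frozen=True)
class PinprickMeasurement:
    """Three detected and two undetected pinprick forces (mN)."""

    yes_intensities: tuple[float, float, float]
    no_intensities: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.yes_intensities) != 3 or len(self.no_intensities) != 2:
            raise InvalidMeasurementError(
                "expected exactly three 'yes' and two 'no' forces"
            )
        for v in (*self.yes_intensities, *self.no_intensities):
            if not (v > 0 and math.isfinite(v)):
                raise InvalidMeasurementError(
                    f"forces must be positive and finite, got {v}"
                )


def pinprick_threshold(m: PinprickMeasurement) -> tuple[float, float]:
    """Geometric mean and log-space SD of the five pinprick forces.

    The SD is the population standard deviation of the natural-log forces,
    back-transformable via ``gm * exp(±sd)``.
    """
    forces = np.array([*m.yes_intensities, *m.no_intensities], dtype=float)
    logs = np.log(forces)
    return float(np.exp(np.mean(logs))), float(np.std(logs))


# ---------------------------------------------------------------------------
# observer simulators


def make_weibull_observer(
    curve: PsychometricCurve,
) -> Callable[[float, np.random.Generator], int]:
    """Stochastic observer responding per the curve's detection probability.

    The returned callback takes linear mA and an explicit RNG; zero
    intensity responds at the curve floor (guess rate).
    """

    def observer(intensity_mA: float, rng: np.random.Generator) -> int:
        if intensity_mA < 0:
            raise ValueError("intensity must be non-negative")
        if intensity_mA == 0:
            p = curve.floor
        else:
            p = weibull_detection_prob(curve, math.log10(intensity_mA))
        return int(rng.random() < p)

    return observer


def make_step_observer(
    threshold_mA: float,
) -> Callable[[float, np.random.Generator], int]:
    """Deterministic observer detecting iff intensity >= threshold (mA)."""

    def observer(intensity_mA: float, rng: np.random.Generator) -> int:
        return int(intensity_mA >= threshold_mA)

    return observer
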