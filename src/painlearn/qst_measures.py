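"""Cuff-algometry outcome measures: PDT, PTT, temporal summation, CPM.

A pressure cuff inflates at a constant rate (nominally 1 kPa/s, capped at
100 kPa) while the subject rates pain continuously on a 0-10 cm visual
analogue scale (VAS).  The pain detection threshold (PDT) is the pressure
at which the VAS first reaches 1 cm; the pain tolerance threshold (PTT)
is the pressure at which the subject presses the stop button, or 100 kPa
as a conservative estimate when the cap is reached without a stop.

Temporal summation of pain (TSP) uses ten identical cuff pulses: the
first rating is subtracted from all ratings (normalisation), and the
TSP-effect ratio is the mean of the last three normalised ratings over
the mean of the first three.  Conditioned pain modulation (CPM) is the
difference between the PTT under a concurrent conditioning stimulus and
the baseline PTT (positive = inhibitory modulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IncompleteRampError, InvalidMeasurementError

__all__ = [
    "CuffRamp",
    "TSPSeries",
    "TSPResult",
    "extract_pdt",
    "extract_ptt",
    "tsp_ratio",
    "cpm_effect",
]


@dataclass(frozen=True)
class CuffRamp:
    """Sampled cuff inflation: time (s), pressure (kPa), VAS (cm)."""

    time_s: np.ndarray
    pressure_kPa: np.ndarray
    vas_cm: np.ndarray
    stop_event_time: float | None = None
    pressure_cap: float = 100.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        p = np.asarray(self.pressure_kPa, dtype=float)
        v = np.asarray(self.vas_cm, dtype=float)
        if t.size == 0:
            raise InvalidMeasurementError("empty ramp trace")
        if not (t.size == p.size == v.size):
            raise InvalidMeasurementError("ramp columns must align")
        if np.any(np.diff(t) <= 0):
            raise InvalidMeasurementError("time must be strictly increasing")
        if np.any((v < 0) | (v > 10)):
            raise InvalidMeasurementError("VAS must lie in [0, 10] cm")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "pressure_kPa", p)
        object.__setattr__(self, "vas_cm", v)


def extract_pdt(ramp: CuffRamp, vas_threshold: float = 1.0) -> float | None:
    """Pressure at the first VAS crossing of 1 cm, or None if never reached.

    The crossing time is linearly interpolated between samples, and the
    pressure is read off the ramp at that time (also interpolated).
    """
    v = ramp.vas_cm
    if v[0] >= vas_threshold:
        return float(ramp.pressure_kPa[0])
    above = np.nonzero(v >= vas_threshold)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    t0, t1 = ramp.time_s[i - 1], ramp.time_s[i]
    v0, v1 = v[i - 1], v[i]
    t_cross = t0 + (vas_threshold - v0) / (v1 - v0) * (t1 - t0)
    return float(np.interp(t_cross, ramp.time_s, ramp.pressure_kPa))


def extract_ptt(ramp: CuffRamp) -> float:
    """Pressure at the stop event; the cap value if reached without a stop.

    Raises :class:`IncompleteRampError` when the trace ends before either
    a stop event or the pressure cap.
    """
    if ramp.stop_event_time is not None:
        return float(
            np.interp(ramp.stop_event_time, ramp.time_s, ramp.pressure_kPa)
        )
    if float(np.max(ramp.pressure_kPa)) >= ramp.pressure_cap:
        return float(ramp.pressure_cap)
    raise IncompleteRampError(
        "ramp ended without stop event or reaching the pressure cap"
    )


@dataclass(frozen=True)
class TSPSeries:
    """Ten VAS ratings (cm), one per cuff pulse."""

    ratings: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ratings) != 10:
            raise InvalidMeasurementError("TSP series must have 10 ratings")
        if any(not 0 <= r <= 10 for r in self.ratings):
            raise InvalidMeasurementError("VAS ratings must lie in [0, 10]")


@dataclass(frozen=True)
class TSPResult:
    ratio: float | None
    normalized: tuple[float, ...]
    defined: bool


def tsp_ratio(series: TSPSeries, *, normalize: bool = True) -> TSPResult:
    """TSP-effect ratio from ten repeated pulses.

    With ``normalize`` (default) the first rating is subtracted from every
    rating (pulse 1 contributes 0 to the early mean); the ratio is
    mean(pulses 8-10) / mean(pulses 1-3) on the normalised series.  A zero
    early-pulse mean makes the ratio undefined (``defined`` False).  Set
    ``normalize=False`` to take the ratio on the raw ratings.
    """
    r = np.asarray(series.ratings, dtype=float)
    work = r - r[0] if normalize else r
    num = float(np.mean(work[7:10]))
    den = float(np.mean(work[0:3]))
    if den == 0.0:
        return TSPResult(ratio=None, normalized=tuple(work), defined=False)
    return TSPResult(ratio=num / den, normalized=tuple(work), defined=True)


def cpm_effect(ptt_conditioned: float, ptt_baseline: float) -> float:
    """PTT change under conditioning: positive values mean inhibition."""
    if ptt_conditioned <= 0 or ptt_baseline <= 0:
        raise InvalidMeasurementError("PTT values must be positive")
    return float(ptt_conditioned - ptt_baseline)
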