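"""Trial schedule for the conditioning/extinction detection task.

The main task body is 12 blocks of 30 trials.  Four trial types are
administered, named for their expected detection rate under the subject's
own psychometric curve: T75, T50, T25 and T0 (cue only, zero intensity).
Early blocks are contingency-rich (mostly T75 trials paired with the
visual cue: acquisition); across blocks the T75 proportion decreases
non-linearly while zero-intensity trials become dominant (extinction).
Trial order is pseudorandomised within each block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IncompleteSessionError
from .psychophysics import PsychometricCurve, invert_weibull

__all__ = [
    "TrialType",
    "TRIAL_TYPES",
    "BlockComposition",
    "TrialSchedule",
    "DEFAULT_BLOCK_COUNTS",
    "default_block_compositions",
    "derive_trial_intensities",
    "generate_schedule",
    "schedule_counts",
    "detection_rates",
]


@dataclass(frozen=True)
class TrialType:
    label: str
    expected_rate: float


T75 = TrialType("T75", 0.75)
T50 = TrialType("T50", 0.50)
T25 = TrialType("T25", 0.25)
T0 = TrialType("T0", 0.0)

TRIAL_TYPES: tuple[TrialType, ...] = (T75, T50, T25, T0)
_BY_LABEL = {t.label: t for t in TRIAL_TYPES}

#: (T75, T50, T25, T0) counts per block.  Blocks 1-3 are acquisition
#: (cue-stimulus contingency high); the T75 count then decays non-linearly
#: while zero-intensity trials are progressively over-represented.
DEFAULT_BLOCK_COUNTS: tuple[tuple[int, int, int, int], ...] = (
    (21, 3, 3, 3),
    (21, 3, 3, 3),
    (21, 3, 3, 3),
    (18, 4, 4, 4),
    (15, 4, 4, 7),
    (12, 5, 5, 8),
    (9, 5, 5, 11),
    (7, 5, 5, 13),
    (5, 5, 5, 15),
    (3, 5, 5, 17),
    (2, 4, 5, 19),
    (1, 4, 4, 21),
)


@dataclass(frozen=True)
class BlockComposition:
    """Per-block multiset of trial types; counts must sum to 30."""

    block_index: int
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not 1 <= self.block_index <= len(DEFAULT_BLOCK_COUNTS) + 100:
            raise ValueError("block_index must be positive")
        if set(self.counts) != set(_BY_LABEL):
            raise ValueError("counts must cover exactly the four trial types")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if sum(self.counts.values()) != 30:
            raise ValueError("block counts must sum to exactly 30")


def default_block_compositions() -> list[BlockComposition]:
    """The default 12-block composition table."""
    return [
        BlockComposition(
            block_index=i + 1,
            counts={"T75": a, "T50": b, "T25": c, "T0": d},
        )
        for i, (a, b, c, d) in enumerate(DEFAULT_BLOCK_COUNTS)
    ]


def derive_trial_intensities(curve: PsychometricCurve) -> dict[str, float]:
    """Stimulus intensity (linear mA) per trial type from the curve.

    T75/T50/T25 invert the psychometric function at 0.75/0.50/0.25; T0 is
    the cue-only zero-intensity trial.
    """
    out = {
        t.label: 10.0 ** invert_weibull(curve, t.expected_rate)
        for t in (T75, T50, T25)
    }
    out["T0"] = 0.0
    return out


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered trial table for one task run.

    ``trials`` has columns block, trial, trial_type, intensity_mA, cue
    (trial is 1-based within block; cue is 1 on every main-body trial,
    including zero-intensity cue-only trials).  Break positions and the
    response window are carried as metadata only.
    """

    trials: pd.DataFrame
    break_after_blocks: tuple[int, ...] = (3, 6, 9)
    response_window_s: float = 4.0

    def __post_init__(self) -> None:
        required = {"block", "trial", "trial_type", "intensity_mA", "cue"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"schedule missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.trials)


def generate_schedule(
    comps: Sequence[BlockComposition],
    intensities: Mapping[str, float],
    seed: int | None = None,
) -> TrialSchedule:
    """Pseudorandomised schedule: seeded permutation of types within blocks."""
    rng = np.random.default_rng(seed)
    rows = []
    for comp in comps:
        labels = [
            lab for lab in ("T75", "T50", "T25", "T0")
            for _ in range(comp.counts[lab])
        ]
        order = rng.permutation(len(labels))
        for trial_idx, j in enumerate(order, start=1):
            lab = labels[j]
            rows.append(
                {
                    "block": comp.block_index,
                    "trial": trial_idx,
                    "trial_type": lab,
                    "intensity_mA": float(intensities[lab]),
                    "cue": 1,
                }
            )
    return TrialSchedule(trials=pd.DataFrame(rows))


def schedule_counts(schedule: TrialSchedule) -> pd.DataFrame:
    """Block-by-type trial counts (rows: block, columns: trial type)."""
    tab = (
        schedule.trials.groupby(["block", "trial_type"])
        .size()
        .unstack(fill_value=0)
    )
    return tab.reindex(columns=["T75", "T50", "T25", "T0"], fill_value=0)


def detection_rates(session) -> pd.DataFrame:
    """Observed detection rate per trial type for a completed session.

    ``session`` is any object with a ``schedule`` (:class:`TrialSchedule`)
    and a ``responses`` sequence of one binary response per trial.  Types
    with no trials get rate NaN and ``defined`` False.
    """
    trials = session.schedule.trials
    responses = np.asarray(session.responses)
    if len(responses) != len(trials):
        raise IncompleteSessionError(
            f"{len(trials)} trials but {len(responses)} responses"
        )
    if not np.isin(responses, (0, 1)).all():
        raise IncompleteSessionError("responses must be binary 0/1")
    out = []
    df = trials.assign(response=responses)
    for t in TRIAL_TYPES:
        sub = df[df.trial_type == t.label]
        n = len(sub)
        rate = float(sub.response.mean()) if n else float("nan")
        out.append(
            {
                "trial_type": t.label,
                "expected_rate": t.expected_rate,
                "n_trials": n,
                "n_detected": int(sub.response.sum()) if n else 0,
                "rate": rate,
                "defined": bool(n),
            }
        )
    return pd.DataFrame(out).set_index("trial_type")
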