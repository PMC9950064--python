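"""File formats, configuration and seed bookkeeping.

One flat CSV dialect (UTF-8, header row, comma-separated) is used for
every table the toolkit reads or writes; configuration round-trips
through YAML or JSON.  A single master seed expands into named
substreams so each pipeline stage (schedule, responses, optimisation
starts, Monte-Carlo sampling) is independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import IncompleteSessionError, SchemaError
from .psychophysics import StaircasePair
from .response_model import Session
from .task_schedule import TrialSchedule

__all__ = [
    "substream_seed",
    "substream_rng",
    "read_session",
    "write_session",
    "write_schedule",
    "read_schedule",
    "write_quest_trace",
    "load_config",
    "save_config",
]

SESSION_COLUMNS = ["subject_id", "block", "trial", "trial_type",
                   "intensity_mA", "cue", "response"]
SCHEDULE_COLUMNS = ["subject_id", "block", "trial", "trial_type",
                    "intensity_mA", "cue"]


def substream_seed(master_seed: int, name: str) -> int:
    """Deterministic named substream seed derived from a master seed.

    Stable across runs and platforms (CRC32 of the name mixed into a
    SeedSequence); always below 2**31.
    """
    ss = np.random.SeedSequence([master_seed, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def substream_rng(master_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(master_seed, name))


def _schedule_frame(schedule: TrialSchedule, subject_id: str) -> pd.DataFrame:
    df = schedule.trials.copy()
    df.insert(0, "subject_id", subject_id)
    return df[SCHEDULE_COLUMNS]


def write_schedule(path, schedule: TrialSchedule, subject_id: str = "sim") -> None:
    _schedule_frame(schedule, subject_id).to_csv(path, index=False)


def read_schedule(path) -> TrialSchedule:
    df = pd.read_csv(path)
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"schedule file missing columns {sorted(missing)}")
    return TrialSchedule(
        trials=df[["block", "trial", "trial_type", "intensity_mA", "cue"]]
    )


def write_session(path, session: Session) -> None:
    df = _schedule_frame(session.schedule, session.subject_id)
    df["response"] = list(session.responses)
    df.to_csv(path, index=False)


def read_session(path) -> Session:
    """Read a session CSV, validating the schema row by row.

    Rejects missing columns, non-binary responses and duplicate
    (block, trial) keys, naming the offending rows.
    """
    df = pd.read_csv(path)
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"session file missing columns {sorted(missing)}")
    if df.empty:
        raise IncompleteSessionError("session file contains no trials")
    bad = df.index[~df.response.isin([0, 1])].tolist()
    if bad:
        raise SchemaError(
            f"non-binary response in rows {[i + 2 for i in bad]} "
            "(1-based, counting the header)"
        )
    dup = df.duplicated(subset=["block", "trial"])
    if dup.any():
        rows = df.index[dup].tolist()
        raise SchemaError(
            f"duplicate (block, trial) keys in rows {[i + 2 for i in rows]}"
        )
    schedule = TrialSchedule(
        trials=df[["block", "trial", "trial_type", "intensity_mA", "cue"]]
        .reset_index(drop=True)
    )
    subject = str(df.subject_id.iloc[0])
    return Session(
        schedule=schedule,
        responses=tuple(int(r) for r in df.response),
        subject_id=subject,
    )


def write_quest_trace(path, pair: StaircasePair, posteriors=None) -> None:
    """Staircase traces as CSV: staircase_id, trial, intensity_mA, response.

    ``posteriors`` are the two final QUEST posteriors whose trial
    histories carry the responses; without them the response column is
    left empty.
    """
    rows = []
    for s, (sid, trace) in enumerate(
        (("a", pair.staircase_a), ("b", pair.staircase_b))
    ):
        history = posteriors[s].trial_history if posteriors else None
        for k, x in enumerate(trace, start=1):
            rows.append(
                {
                    "staircase_id": sid,
                    "trial": k,
                    "intensity_mA": x,
                    "response": history[k - 1][1] if history else None,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file by extension."""
    p = Path(path)
    text = p.read_text()
    if p.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(path, config: Mapping) -> None:
    p = Path(path)
    if p.suffix in (".yaml", ".yml"):
        p.write_text(yaml.safe_dump(dict(config), sort_keys=False))
    else:
        p.write_text(json.dumps(dict(config), indent=2))
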