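"""File round-tripping: the trial CSV dialect, result JSON/CSV, YAML configs.

The trial CSV has one row per trial with columns
participant, session, block, trial, target_pos, d1, d2, d3, config, color,
notch, response, correct, rt_s — rt_s (and response/correct) empty on
no-response trials. Sessions are grouped by (participant, session) and kept
in trial order; every loaded session is validated against the task
invariants.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .paradigm import (
    Configuration,
    SessionData,
    TrialOutcome,
    TrialStimulus,
    validate_session,
)

__all__ = ["read_trials", "write_trials", "sessions_to_frame", "write_json", "load_config"]

CSV_COLUMNS = [
    "participant", "session", "block", "trial", "target_pos",
    "d1", "d2", "d3", "config", "color", "notch", "response", "correct", "rt_s",
]


def sessions_to_frame(sessions: list[SessionData]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for stim, out in s.trials:
            d1, d2, d3 = sorted(stim.distractor_positions)
            rows.append(
                {
                    "participant": s.participant,
                    "session": s.session,
                    "block": stim.block_index,
                    "trial": stim.trial_index,
                    "target_pos": stim.target_position,
                    "d1": d1, "d2": d2, "d3": d3,
                    "config": Configuration(stim.configuration).value,
                    "color": stim.target_color,
                    "notch": stim.notch,
                    "response": "" if out.response is None else out.response,
                    "correct": "" if out.correct is None else int(out.correct),
                    "rt_s": "" if out.rt is None else out.rt,
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_trials(sessions: list[SessionData], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_trials(path, force: bool = False) -> list[SessionData]:
    """Load sessions from the trial CSV dialect, validating invariants.

    Raises on any invariant violation unless ``force`` is set (violations
    are then ignored after being collected).
    """
    df = pd.read_csv(path, dtype={"participant": str, "session": str}, keep_default_na=False)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns {sorted(missing)}")
    sessions = []
    problems: list[str] = []
    for (pid, sid), g in df.groupby(["participant", "session"], sort=False):
        g = g.sort_values("trial")
        trials = []
        for _, row in g.iterrows():
            try:
                stim = TrialStimulus(
                    trial_index=int(row["trial"]),
                    block_index=int(row["block"]),
                    target_position=int(row["target_pos"]),
                    distractor_positions=frozenset(
                        (int(row["d1"]), int(row["d2"]), int(row["d3"]))
                    ),
                    configuration=Configuration(row["config"]),
                    target_color=str(row["color"]),
                    notch=str(row["notch"]),
                )
            except (KeyError, ValueError) as e:
                raise ValueError(f"malformed row for trial {row['trial']} "
                                 f"({pid}/{sid}): {e}") from e
            rt = row["rt_s"]
            if rt == "" or (isinstance(rt, float) and np.isnan(rt)):
                out = TrialOutcome(None, None, None)
            else:
                out = TrialOutcome(
                    response=str(row["response"]),
                    correct=bool(int(row["correct"])),
                    rt=float(rt),
                )
            trials.append((stim, out))
        session = SessionData(participant=str(pid), session=str(sid), trials=trials)
        v = validate_session(session)
        if v:
            problems.extend(f"{pid}/{sid}: {msg}" for msg in v)
        sessions.append(session)
    if problems and not force:
        raise ValueError("invalid sessions:\n" + "\n".join(problems))
    return sessions


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if hasattr(x, "to_dict"):
        return x.to_dict()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
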