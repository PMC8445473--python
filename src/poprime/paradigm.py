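"""Domain types for the priming-of-pop-out (PoP) search task.

The task: four items occupy four of eight positions on a virtual circle,
forming either a *square* (even positions, by our convention) or a *diamond*
(odd positions). One item, the target, is the odd-one-out in color; the
response is determined by a notch cut from the top or bottom of the target
(the response-critical feature, RCF). Three aspects of stimulus history
drive inter-trial priming: the target color polarity, the target position,
and the RCF.

Positions are indexed 0-7 clockwise from the top of the circle. Because all
updating rules depend only on circular distance and position identity, any
fixed indexing convention is equivalent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

N_POSITIONS = 8

__all__ = [
    "N_POSITIONS",
    "Configuration",
    "TrialStimulus",
    "TrialOutcome",
    "SessionData",
    "circular_distance",
    "classify_position_transition",
    "classify_feature_transition",
    "validate_session",
]


class Configuration(str, Enum):
    SQUARE = "square"  # even positions {0, 2, 4, 6}
    DIAMOND = "diamond"  # odd positions {1, 3, 5, 7}


def _config_parity(config: "Configuration | str") -> int:
    return 0 if Configuration(config) is Configuration.SQUARE else 1


@dataclass(frozen=True)
class TrialStimulus:
    """One trial's search display.

    ``target_color`` is the color polarity ('A' = e.g. red target among green
    distractors, 'B' the swap); ``notch`` is the response-critical feature.
    """

    trial_index: int
    block_index: int
    target_position: int
    distractor_positions: frozenset[int]
    configuration: Configuration
    target_color: str  # 'A' | 'B'
    notch: str  # 'top' | 'bottom'

    def occupied_positions(self) -> frozenset[int]:
        return self.distractor_positions | {self.target_position}


@dataclass(frozen=True)
class TrialOutcome:
    """Response, correctness and RT; all missing if no response by deadline."""

    response: Optional[str]  # 'top' | 'bottom' | None
    correct: Optional[bool]
    rt: Optional[float]  # seconds


@dataclass
class SessionData:
    """An ordered sequence of trials from one participant-session.

    Order matters: the updating rules are sequential, and state flows across
    block boundaries within a session.
    """

    participant: str
    session: str
    trials: list[tuple[TrialStimulus, TrialOutcome]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def stimuli(self) -> list[TrialStimulus]:
        return [s for s, _ in self.trials]

    @property
    def outcomes(self) -> list[TrialOutcome]:
        return [o for _, o in self.trials]

    def n_blocks(self) -> int:
        return len({s.block_index for s, _ in self.trials})


def circular_distance(i: int, j: int) -> int:
    """Shortest distance between two positions on the 8-cycle (0-4).

    d = 4 is the position on the opposite side of the circle.
    """
    if not (0 <= i < N_POSITIONS and 0 <= j < N_POSITIONS):
        raise ValueError(f"positions must be in 0-{N_POSITIONS - 1}, got ({i}, {j})")
    d = abs(i - j)
    return min(d, N_POSITIONS - d)


def classify_position_transition(
    current: TrialStimulus, previous: TrialStimulus
) -> str:
    """Classify a (lag-k) ordered pair of trials by the target's position.

    'TT': target at the previous target position; 'TD': at a previous
    distractor position; 'TN': at a previously empty (neutral) position.
    """
    if current.target_position == previous.target_position:
        return "TT"
    if current.target_position in previous.distractor_positions:
        return "TD"
    return "TN"


def classify_feature_transition(
    uv: str, current: TrialStimulus, previous: TrialStimulus
) -> str:
    """'repeat' iff the named feature ('color' or 'rcf') is equal on both trials."""
    if uv == "color":
        same = current.target_color == previous.target_color
    elif uv == "rcf":
        same = current.notch == previous.notch
    else:
        raise ValueError(f"unknown updating variable {uv!r} (expected 'color' or 'rcf')")
    return "repeat" if same else "switch"


def validate_session(session: SessionData) -> list[str]:
    """Check every per-trial invariant; return human-readable violations.

    Reports rather than raises, so that a whole file can be audited in one
    pass. An empty list means the session is well-formed.
    """
    violations: list[str] = []
    prev_index = -math.inf
    for stim, out in session.trials:
        t = stim.trial_index
        if t <= prev_index:
            violations.append(f"trial {t}: trial indices not strictly increasing")
        prev_index = t
        if not (0 <= stim.target_position < N_POSITIONS):
            violations.append(f"trial {t}: target position {stim.target_position} out of range")
        if len(stim.distractor_positions) != 3:
            violations.append(
                f"trial {t}: expected 3 distractors, got {len(stim.distractor_positions)}"
            )
        if stim.target_position in stim.distractor_positions:
            violations.append(f"trial {t}: target position coincides with a distractor")
        parity = _config_parity(stim.configuration)
        occupied = stim.occupied_positions()
        if any(p % 2 != parity for p in occupied):
            violations.append(
                f"trial {t}: occupied positions {sorted(occupied)} violate "
                f"{Configuration(stim.configuration).value} parity"
            )
        if stim.target_color not in ("A", "B"):
            violations.append(f"trial {t}: unknown color {stim.target_color!r}")
        if stim.notch not in ("top", "bottom"):
            violations.append(f"trial {t}: unknown notch {stim.notch!r}")
        if out.rt is not None and not out.rt > 0:
            violations.append(f"trial {t}: non-positive RT {out.rt}")
        if out.response is not None and out.correct is not None:
            if out.correct != (out.response == stim.notch):
                violations.append(f"trial {t}: correctness inconsistent with response/notch")
    return violations


# ---------------------------------------------------------------------------
# Array view used by the sequential machinery (rules, likelihood, simulation).

_COLOR_CODE = {"A": 0, "B": 1}
_NOTCH_CODE = {"top": 0, "bottom": 1}


@dataclass
class SessionArrays:
    """Columnar view of a session for vectorized computation."""

    n: int
    block: np.ndarray  # int, 1-based
    target_pos: np.ndarray  # int 0-7
    distractors: np.ndarray  # (n, 3) int
    config: np.ndarray  # 0 = square, 1 = diamond
    color: np.ndarray  # 0 = A, 1 = B
    notch: np.ndarray  # 0 = top, 1 = bottom
    response: np.ndarray  # -1 missing
    correct: np.ndarray  # bool (False when missing)
    rt: np.ndarray  # float seconds, NaN missing


def stimuli_to_arrays(stims: Sequence[TrialStimulus]) -> SessionArrays:
    """Columnar view of a stimulus sequence (outcomes marked missing)."""
    outs = [TrialOutcome(None, None, None)] * len(stims)
    return _to_arrays(stims, outs)


def session_to_arrays(session: SessionData) -> SessionArrays:
    return _to_arrays(session.stimuli, session.outcomes)


def _to_arrays(stims: Sequence[TrialStimulus], outs: Sequence[TrialOutcome]) -> SessionArrays:
    n = len(stims)
    return SessionArrays(
        n=n,
        block=np.array([s.block_index for s in stims], dtype=np.int64),
        target_pos=np.array([s.target_position for s in stims], dtype=np.int64),
        distractors=np.array(
            [sorted(s.distractor_positions) for s in stims], dtype=np.int64
        ).reshape(n, 3),
        config=np.array([_config_parity(s.configuration) for s in stims], dtype=np.int64),
        color=np.array([_COLOR_CODE[s.target_color] for s in stims], dtype=np.int64),
        notch=np.array([_NOTCH_CODE[s.notch] for s in stims], dtype=np.int64),
        response=np.array(
            [(-1 if o.response is None else _NOTCH_CODE[o.response]) for o in outs],
            dtype=np.int64,
        ),
        correct=np.array([bool(o.correct) for o in outs], dtype=bool),
        rt=np.array([(np.nan if o.rt is None else o.rt) for o in outs], dtype=float),
    )
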