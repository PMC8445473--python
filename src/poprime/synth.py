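"""Synthetic sessions replicating the PoP experimental design.

The original study's raw RT data are not deposited, so every downstream
stage (rules, likelihood, model comparison, profiles) is exercised on
sessions generated here: trial sequences honoring the design's balancing
constraints, and RTs/responses simulated forward from a chosen generative
model with known parameters.

Design constraints emulated: 8 circular positions, 4 items per trial in a
square (even positions) or diamond (odd positions) arrangement; the target
visits each position equally often; positional transitions from trial n-1
to n are equally often TT (previous target position), TD (a previous
distractor position) and TN (a previously empty position); the color
polarity repeats with probability 1/2; the notch is random each trial.
Because a configuration holds exactly the four positions of one parity, a
TN transition occurs exactly when the configuration switches.

The sampler draws transition types from a shuffled balanced deck and picks
target positions greedily to equalize per-position counts (random
tie-breaking) — the constraints fix the marginals, not the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ea import DDMParams, LATERParams, _ddm_paths
from .fitting import ModelSpec, no_update_spec
from .paradigm import (
    Configuration,
    N_POSITIONS,
    SessionData,
    TrialOutcome,
    TrialStimulus,
    stimuli_to_arrays,
)
from .rules import get_rule_spec, run_rules

__all__ = [
    "DesignConstraints",
    "GenerativeSpec",
    "generate_design",
    "simulate_session",
    "simulate_study",
    "generate_fixture_suite",
]

_PARITY_POSITIONS = {0: (0, 2, 4, 6), 1: (1, 3, 5, 7)}


@dataclass(frozen=True)
class DesignConstraints:
    """Counts and balancing constraints of one session's trial sequence."""

    n_blocks: int = 8
    trials_per_block: int = 112
    color_repeat_probability: float = 0.5
    notch_probability: float = 0.5
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def __post_init__(self):
        if self.n_blocks < 1 or self.trials_per_block < 3:
            raise ValueError("need at least 1 block of at least 3 trials")
        if self.n_trials < 24:
            raise ValueError("fewer than 24 trials: transition balancing is meaningless")
        for p in (self.color_repeat_probability, self.notch_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class GenerativeSpec:
    """A ground-truth model for forward simulation.

    ``rule_params`` maps uv -> parameter dict for the (non-trivial) rules in
    ``model``. LATER has no intrinsic error mechanism, so ``lapse_probability``
    produces uniform-random responses; DDM errors are wrong-boundary
    absorptions. The deadline censors slow trials (missing outcome) and is
    set to the 1.5-s outlier bound so censoring and exclusion coincide.
    """

    model: ModelSpec
    ea_params: object  # LATERParams | DDMParams
    rule_params: dict = field(default_factory=dict)
    lapse_probability: float = 0.0
    deadline: float = 1.5

    def __post_init__(self):
        self.ea_params.validate()
        if not 0.0 <= self.lapse_probability <= 1.0:
            raise ValueError("lapse_probability must lie in [0, 1]")


def _balanced_deck(n: int, rng) -> list[str]:
    kinds = ["TT", "TD", "TN"]
    base, extra = divmod(n, 3)
    deck = kinds * base + list(rng.permutation(kinds)[:extra])
    rng.shuffle(deck)
    return deck


def _greedy_pick(candidates, counts, rng) -> int:
    c = np.asarray(list(candidates))
    best = c[counts[c] == counts[c].min()]
    return int(rng.choice(best))


def generate_design(c: DesignConstraints) -> list[TrialStimulus]:
    """Generate one session's stimulus sequence under the design constraints.

    Per session the TT/TD/TN counts differ by at most 1 (balanced deck);
    per-position target counts are equalized greedily (TT transitions force
    the position, so the balance carries a small slack).
    """
    rng = np.random.default_rng(c.seed)
    n = c.n_trials
    deck = _balanced_deck(n - 1, rng)
    counts = np.zeros(N_POSITIONS, dtype=int)

    parity = int(rng.integers(2))
    target = _greedy_pick(_PARITY_POSITIONS[parity], counts, rng)
    color = "A" if rng.random() < 0.5 else "B"
    stimuli = []
    for i in range(n):
        if i > 0:
            kind = deck[i - 1]
            prev_target = target
            if kind == "TT":
                pass  # same configuration, same position
            elif kind == "TD":
                options = [p for p in _PARITY_POSITIONS[parity] if p != prev_target]
                target = _greedy_pick(options, counts, rng)
            else:  # TN: a parity switch vacates all previously occupied positions
                parity = 1 - parity
                target = _greedy_pick(_PARITY_POSITIONS[parity], counts, rng)
            if rng.random() >= c.color_repeat_probability:
                color = "B" if color == "A" else "A"
        counts[target] += 1
        distractors = frozenset(p for p in _PARITY_POSITIONS[parity] if p != target)
        stimuli.append(
            TrialStimulus(
                trial_index=i + 1,
                block_index=i // c.trials_per_block + 1,
                target_position=target,
                distractor_positions=distractors,
                configuration=Configuration.SQUARE if parity == 0 else Configuration.DIAMOND,
                target_color=color,
                notch="top" if rng.random() < c.notch_probability else "bottom",
            )
        )
    return stimuli


_START_EPS = 1e-3


def simulate_session(
    design: list[TrialStimulus],
    g: GenerativeSpec,
    seed: int,
    participant: str = "sim",
    session: str = "1",
    grid_size: int = 101,
) -> SessionData:
    """Simulate responses and RTs for a stimulus sequence.

    Per trial: the active rules' states (accumulated over all previous
    trials, error and censored trials included) yield a modulation; an RT is
    sampled from the modulated EA model plus NDT; responses beyond the
    deadline are censored to a missing outcome. Rule states depend only on
    the stimuli, so the sequential pass and the sampling are separable.
    """
    rng = np.random.default_rng(seed)
    arrays = stimuli_to_arrays(design)
    active = [
        (rule, g.rule_params.get(rule.uv, {}))
        for rule in g.model.rules
        if rule.rule_id != 1
    ]
    ds0, scale, dndt = run_rules(arrays, active, grid_size=grid_size)
    p = g.ea_params
    n = arrays.n
    tau_eff = np.maximum(p.tau + dndt, 0.0)

    if g.model.ea_model == "LATER":
        d = p.theta - (p.s0_base + ds0)
        if np.any(d <= 0):
            raise ValueError("generative starting point reached the boundary")
        mu = scale * p.mu_r
        a = (0.0 - mu) / p.sigma_r
        r = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=p.sigma_r, size=n, random_state=rng)
        rt = tau_eff + d / r
        lapse = rng.random(n) < g.lapse_probability
        coin = rng.integers(2, size=n)
        resp = np.where(lapse, coin, arrays.notch)
    else:
        z = np.clip(
            p.theta / 2.0 + p.s0_base + ds0, _START_EPS * p.theta, (1.0 - _START_EPS) * p.theta
        )
        fpt, hit_upper = _ddm_paths(z, scale * p.r, p.theta, p.s, rng, t_max=g.deadline)
        rt = tau_eff + fpt
        resp = np.where(hit_upper, arrays.notch, 1 - arrays.notch)

    notch_names = np.array(["top", "bottom"])
    trials = []
    for i, stim in enumerate(design):
        if rt[i] > g.deadline:
            out = TrialOutcome(None, None, None)
        else:
            response = str(notch_names[resp[i]])
            out = TrialOutcome(response, response == stim.notch, float(rt[i]))
        trials.append((stim, out))
    return SessionData(participant=participant, session=session, trials=trials)


def simulate_study(
    g: GenerativeSpec,
    n_participants: int,
    n_sessions: int = 2,
    constraints: DesignConstraints | None = None,
    seed: int = 0,
) -> list[SessionData]:
    """Simulate a multi-participant study; rule states reset every session."""
    constraints = constraints or DesignConstraints()
    sessions = []
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=(n_participants, n_sessions, 2))
    for i in range(n_participants):
        for j in range(n_sessions):
            design = generate_design(
                DesignConstraints(
                    n_blocks=constraints.n_blocks,
                    trials_per_block=constraints.trials_per_block,
                    color_repeat_probability=constraints.color_repeat_probability,
                    notch_probability=constraints.notch_probability,
                    seed=int(base[i, j, 0]),
                )
            )
            sessions.append(
                simulate_session(
                    design, g, seed=int(base[i, j, 1]),
                    participant=f"p{i + 1:02d}", session=str(j + 1),
                )
            )
    return sessions


# ---------------------------------------------------------------------------
# Hand-checkable 8-trial fixtures


def _fixed_stimuli(targets, parities, colors, notches) -> list[TrialStimulus]:
    stimuli = []
    for i, (t, par, col, no) in enumerate(zip(targets, parities, colors, notches)):
        stimuli.append(
            TrialStimulus(
                trial_index=i + 1,
                block_index=1,
                target_position=t,
                distractor_positions=frozenset(p for p in _PARITY_POSITIONS[par] if p != t),
                configuration=Configuration.SQUARE if par == 0 else Configuration.DIAMOND,
                target_color=col,
                notch=no,
            )
        )
    return stimuli


def generate_fixture_suite(seed: int = 0) -> dict[str, SessionData]:
    """Three 8-trial sequences whose rule dynamics can be checked by hand.

    'color': target-color pattern repeat/repeat/switch/repeat/switch/switch/
    switch over trials 2-8 (two repeats in a row, then a long run of the
    other color, so the weighted-rate weight is higher on trial 3 than on
    trial 2 and clearly lower on trial 5).
    'position': constant square configuration with TD transitions on trials
    4 and 7; the trial-7 target position has hosted distractors throughout,
    so distractor inhibition leaves it a lower weight than the trial-4 one.
    'rcf': a target-position repeat combined with a notch switch at trial 2.
    """
    rng = np.random.default_rng(seed)

    colors_a = ["A", "A", "A", "B", "B", "A", "B", "A"]
    stim_a = _fixed_stimuli(
        targets=[0] * 8,
        parities=[0] * 8,
        colors=colors_a,
        notches=[str(np.array(["top", "bottom"])[rng.integers(2)]) for _ in range(8)],
    )

    targets_b = [0, 0, 0, 2, 2, 2, 4, 4]  # TD at trials 4 and 7
    stim_b = _fixed_stimuli(
        targets=targets_b,
        parities=[0] * 8,
        colors=["A"] * 8,
        notches=["top"] * 8,
    )

    notches_c = ["top", "bottom", "top", "top", "bottom", "top", "bottom", "top"]
    stim_c = _fixed_stimuli(
        targets=[2, 2, 4, 6, 0, 2, 4, 6],  # position repeat at trial 2
        parities=[0] * 8,
        colors=["A"] * 8,
        notches=notches_c,
    )

    out = {}
    for name, stims in (("color", stim_a), ("position", stim_b), ("rcf", stim_c)):
        trials = [(s, TrialOutcome(None, None, None)) for s in stims]
        out[name] = SessionData(participant=f"fixture-{name}", session="1", trials=trials)
    return out


def weighted_rate_color_spec(ea_model: str = "LATER") -> ModelSpec:
    """LATER/DDM with the winning color rule only (convenience for recovery)."""
    base = no_update_spec(ea_model)
    from dataclasses import replace

    return replace(base, color_rule=get_rule_spec("color", "weighted_rate"))
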