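"""Trial-history updating rules for the evidence-accumulation parameters.

Each rule watches one *updating variable* (UV) — the response-critical
feature (RCF, notch top/bottom), the target color polarity, or the target
position — and modulates one parameter of the evidence-accumulation model:
the starting point S0, the accumulation rate, or the non-decision time (NDT).

Rule families
-------------
* Bayesian S0 rules learn the relative frequency of the two UV states by
  Bayesian updating of a (discretized) Beta belief with forgetting as in the
  dynamic belief model: after each trial the belief is mixed back toward the
  starting distribution with weight 1 - alpha. The starting point on a trial
  is the log prior odds of the UV state that actually occurs. Variants
  differ in position specificity: position-independent (PI), fully
  position-dependent (PD), a distance gradient (PG, likelihood blended with
  a flat likelihood by omega**d), and position-spreading (PS, Gaussian
  spatial mixing of the per-position beliefs before each update).
* Binary rules depend only on whether the UV repeated from the immediately
  preceding trial (a one-back baseline).
* Step rules carry repetition/switch increments across trials with
  exponential forgetting.
* Weighted rules redistribute a fixed total "weight" resource over the UV
  levels after every trial (weights sum to N for rate rules; NDT offsets
  sum to 0), with forgetting toward the uniform start. The position rules
  additionally support distractor inhibition, either with independent
  target/distractor budgets (zero-sum over all eight positions) or exactly
  matched (weight moves only between target and distractor positions).

State updates depend only on the stimulus sequence, never on responses or
RTs, and are applied on every trial — including error and censored trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .paradigm import N_POSITIONS, SessionArrays, circular_distance

__all__ = [
    "RuleSpec",
    "Trial",
    "registry_levels",
    "get_rule_spec",
    "make_rule",
    "run_rules",
    "s0_from_belief",
    "bayes_update_grid",
    "dbm_mix",
    "belief_grid",
    "beta_prior_on_grid",
    "NO_UPDATE",
]

# parameter boxes (shared convention with the fitting module)
_BOUNDS = {
    "alpha": (0.0, 0.999),
    "beta0": (0.5, 50.0),
    "omega": (0.01, 0.99),
    "sigma_spread": (0.1, 4.0),
    "kappa": (0.2, 1.0),
    "delta_rate": (0.0, 1.0),
    "delta_ndt": (0.0, 0.2),
}


@dataclass(frozen=True)
class RuleSpec:
    """Identity and parameter layout of one updating rule."""

    uv: str  # 'rcf' | 'color' | 'position'
    rule_id: int  # 1-18
    name: str
    target: str  # 's0' | 'rate' | 'ndt' | 'none'
    param_names: tuple[str, ...]
    param_bounds: tuple[tuple[float, float], ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def key(self) -> str:
        return f"{self.uv}:{self.name}"


def _spec(uv: str, rule_id: int, name: str, target: str, *params: str) -> RuleSpec:
    bounds = []
    for p in params:
        if p.startswith("delta"):
            bounds.append(_BOUNDS["delta_ndt" if target == "ndt" else "delta_rate"])
        else:
            bounds.append(_BOUNDS[p])
    return RuleSpec(uv, rule_id, name, target, tuple(params), tuple(bounds))


def _registry() -> dict[str, list[RuleSpec]]:
    rcf = [
        _spec("rcf", 1, "no_update", "none"),
        _spec("rcf", 2, "pi_bayes_s0", "s0", "alpha", "beta0"),
        _spec("rcf", 3, "pd_bayes_s0", "s0", "alpha", "beta0"),
        _spec("rcf", 4, "pg_bayes_s0", "s0", "alpha", "omega", "beta0"),
        _spec("rcf", 5, "ps_bayes_s0", "s0", "alpha", "sigma_spread", "beta0"),
        _spec("rcf", 6, "binary_rate", "rate", "kappa"),
        _spec("rcf", 7, "step_rate", "rate", "alpha", "delta"),
        _spec("rcf", 8, "weighted_rate", "rate", "alpha", "delta"),
        _spec("rcf", 11, "binary_ndt", "ndt", "delta"),
        _spec("rcf", 12, "weighted_ndt", "ndt", "alpha", "delta"),
        _spec("rcf", 15, "pd_step_ndt", "ndt", "alpha", "delta"),
        _spec("rcf", 16, "pg_step_ndt", "ndt", "alpha", "omega", "delta"),
    ]
    color = [
        _spec("color", 1, "no_update", "none"),
        _spec("color", 6, "binary_rate", "rate", "kappa"),
        _spec("color", 7, "step_rate", "rate", "alpha", "delta"),
        _spec("color", 8, "weighted_rate", "rate", "alpha", "delta"),
        _spec("color", 17, "pd_weighted_rate", "rate", "alpha", "delta"),
        _spec("color", 18, "pg_weighted_rate", "rate", "alpha", "omega", "delta"),
        _spec("color", 11, "binary_ndt", "ndt", "delta"),
        _spec("color", 12, "weighted_ndt", "ndt", "alpha", "delta"),
    ]
    position = [
        _spec("position", 1, "no_update", "none"),
        _spec("position", 6, "binary_rate", "rate", "kappa"),
        _spec("position", 7, "step_rate", "rate", "alpha", "delta"),
        _spec("position", 8, "weighted_rate", "rate", "alpha", "delta"),
        _spec("position", 9, "weighted_rate_di", "rate", "alpha", "delta_t", "delta_d"),
        _spec("position", 10, "weighted_rate_matched", "rate", "alpha", "delta"),
        _spec("position", 11, "binary_ndt", "ndt", "delta"),
        _spec("position", 12, "weighted_ndt", "ndt", "alpha", "delta"),
        _spec("position", 13, "weighted_ndt_di", "ndt", "alpha", "delta_t", "delta_d"),
        _spec("position", 14, "weighted_ndt_matched", "ndt", "alpha", "delta"),
    ]
    return {"rcf": rcf, "color": color, "position": position}


_REGISTRY = _registry()


def registry_levels(uv: str) -> list[RuleSpec]:
    """Ordered factor levels for one updating variable (12 / 8 / 10 levels)."""
    try:
        return list(_REGISTRY[uv])
    except KeyError:
        raise ValueError(f"unknown updating variable {uv!r}") from None


def get_rule_spec(uv: str, name: str) -> RuleSpec:
    for spec in registry_levels(uv):
        if spec.name == name:
            return spec
    raise ValueError(f"no rule named {name!r} for uv {uv!r}")


NO_UPDATE = {uv: _REGISTRY[uv][0] for uv in _REGISTRY}

# circular-distance matrix between the 8 positions
_DIST = np.array(
    [[circular_distance(i, j) for j in range(N_POSITIONS)] for i in range(N_POSITIONS)],
    dtype=float,
)


@dataclass(frozen=True)
class Trial:
    """The stimulus facts a rule may condition on, for one trial."""

    uv_value: int  # level index of this rule's UV on the current trial
    rep: Optional[bool]  # UV repeated from trial n-1 (None on the first trial)
    target_pos: int
    distractors: np.ndarray  # (3,) int


# ---------------------------------------------------------------------------
# Discretized-Beta belief machinery (Bayesian S0 rules)


def belief_grid(size: int = 101) -> np.ndarray:
    """Midpoint grid on (0, 1) for the Bernoulli parameter.

    Midpoints avoid the endpoint singularities of Beta(b, b) for b < 1 and
    keep posterior-predictive probabilities strictly inside (0, 1).
    """
    return (np.arange(size) + 0.5) / size


def beta_prior_on_grid(grid: np.ndarray, beta0: float) -> np.ndarray:
    w = grid ** (beta0 - 1.0) * (1.0 - grid) ** (beta0 - 1.0)
    return w / w.sum()


def bayes_update_grid(belief: np.ndarray, likelihood: np.ndarray) -> np.ndarray:
    """One Bayes step on the grid; returns the normalized posterior."""
    post = belief * likelihood
    total = post.sum(axis=-1, keepdims=True)
    return post / total


def dbm_mix(belief: np.ndarray, prior0: np.ndarray, alpha: float) -> np.ndarray:
    """Dynamic-belief-model forgetting: redraw from the start with prob 1 - alpha."""
    return alpha * belief + (1.0 - alpha) * prior0


def s0_from_belief(belief: np.ndarray, grid: np.ndarray, value_is_h: bool) -> float:
    """Log prior odds of the UV state that occurs on the current trial.

    P is the posterior-predictive probability of state H (the grid mean of
    the belief); positive output = head start toward the correct boundary.
    """
    p = float(np.sum(belief * grid))
    if not value_is_h:
        p = 1.0 - p
    # grid midpoints keep p strictly inside (0, 1); clip defensively anyway
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    return float(np.log(p / (1.0 - p)))


# ---------------------------------------------------------------------------
# Rule engines. Each engine owns its state and exposes step(trial), applying
# the rule's read/update ordering: belief and weighted rules read the state
# accumulated through trial n-1 and then update; binary and step rules first
# incorporate the current repetition indicator, then read (a value-agnostic
# scalar applied blind would predict no one-back effect).


class _RuleBase:
    spec: RuleSpec

    def __init__(self, spec: RuleSpec, params: dict, validate: bool = True):
        self.spec = spec
        missing = set(spec.param_names) - set(params)
        if missing:
            raise ValueError(f"rule {spec.key} missing parameters {sorted(missing)}")
        self.params = {k: float(params[k]) for k in spec.param_names}
        if validate:
            self._check_admissible()

    # mathematically admissible ranges (wider than the fitting boxes, which
    # stop short of degenerate boundaries for the optimizer's sake)
    def _check_admissible(self):
        p, key = self.params, self.spec.key
        if "alpha" in p and not 0.0 <= p["alpha"] <= 1.0:
            raise ValueError(f"{key}: alpha must lie in [0, 1]")
        if "beta0" in p and not p["beta0"] > 0.0:
            raise ValueError(f"{key}: beta0 must be positive")
        if "omega" in p and not 0.0 < p["omega"] < 1.0:
            raise ValueError(f"{key}: omega must lie strictly inside (0, 1)")
        if "sigma_spread" in p and not p["sigma_spread"] > 0.0:
            raise ValueError(f"{key}: sigma_spread must be positive")
        if "kappa" in p and not 0.0 < p["kappa"] <= 1.0:
            raise ValueError(f"{key}: kappa must lie in (0, 1]")
        for name in ("delta", "delta_t", "delta_d"):
            if name in p and p[name] < 0.0:
                raise ValueError(f"{key}: {name} must be non-negative")

    def step(self, tr: Trial) -> tuple[float, float, float]:
        raise NotImplementedError

    def state_vector(self) -> np.ndarray:
        """Flat copy of the internal state (for continuity checks)."""
        return np.zeros(0)


class NoUpdate(_RuleBase):
    def step(self, tr: Trial):
        return 0.0, 1.0, 0.0


class BayesS0(_RuleBase):
    """Rules 2-5: Bayesian starting-point updating with DBM forgetting."""

    def __init__(self, spec, params, grid_size: int = 101, validate: bool = True):
        super().__init__(spec, params, validate)
        self.grid = belief_grid(grid_size)
        self.prior0 = beta_prior_on_grid(self.grid, self.params["beta0"])
        self.variant = {2: "pi", 3: "pd", 4: "pg", 5: "ps"}[spec.rule_id]
        if self.variant == "pi":
            self.belief = self.prior0.copy()
        else:
            self.belief = np.tile(self.prior0, (N_POSITIONS, 1))
        if self.variant == "ps":
            sig = self.params["sigma_spread"]
            w = np.exp(-(_DIST**2) / (2.0 * sig**2))
            self.spread = w / w.sum(axis=1, keepdims=True)

    def _likelihood(self, value: int) -> np.ndarray:
        # state H := UV level 0; Bernoulli likelihood on the grid
        return self.grid if value == 0 else 1.0 - self.grid

    def step(self, tr: Trial):
        a = self.params["alpha"]
        if self.variant == "pi":
            ds0 = s0_from_belief(self.belief, self.grid, tr.uv_value == 0)
            self.belief = dbm_mix(
                bayes_update_grid(self.belief, self._likelihood(tr.uv_value)),
                self.prior0,
                a,
            )
            return ds0, 1.0, 0.0

        ds0 = s0_from_belief(self.belief[tr.target_pos], self.grid, tr.uv_value == 0)
        if self.variant == "ps":
            # spreading happens after the read-out, before the Bayes step
            self.belief = self.spread @ self.belief
        if self.variant in ("pd", "ps"):
            self.belief[tr.target_pos] = bayes_update_grid(
                self.belief[tr.target_pos], self._likelihood(tr.uv_value)
            )
        elif self.variant == "pg":
            om = self.params["omega"]
            q = self._likelihood(tr.uv_value)
            wd = om ** _DIST[:, tr.target_pos]
            blended = wd[:, None] * q[None, :] + (1.0 - wd[:, None]) / 2.0
            self.belief = bayes_update_grid(self.belief, blended)
        self.belief = dbm_mix(self.belief, self.prior0[None, :], a)
        return ds0, 1.0, 0.0

    def state_vector(self):
        return np.ravel(self.belief).copy()


class BinaryRate(_RuleBase):
    """Rule 6: rate scaled by kappa < 1 when the UV switched from n-1."""

    def step(self, tr: Trial):
        scale = 1.0 if tr.rep is None or tr.rep else self.params["kappa"]
        return 0.0, scale, 0.0


class StepRate(_RuleBase):
    """Rule 7: scalar rate scale, +/- delta per repetition/switch, decay to 1."""

    def __init__(self, spec, params, validate: bool = True):
        super().__init__(spec, params, validate)
        self.kappa = 1.0

    def step(self, tr: Trial):
        a, d = self.params["alpha"], self.params["delta"]
        if tr.rep is not None:
            self.kappa = a * (self.kappa + (2.0 * tr.rep - 1.0) * d) + (1.0 - a)
        return 0.0, self.kappa, 0.0

    def state_vector(self):
        return np.array([self.kappa])


class WeightedRate(_RuleBase):
    """Rules 8/9/10: weight resource over UV levels scaling the rate.

    Rule 9 adds an independent distractor-inhibition budget (zero-sum over
    all eight positions); rule 10 moves weight only from the distractor
    positions to the target. ``literal_eq10`` reproduces the printed (non
    zero-sum) form of the distractor term for rule 9.
    """

    def __init__(self, spec, params, n_levels: int, literal_eq10: bool = False,
                 validate: bool = True):
        super().__init__(spec, params, validate)
        self.n = n_levels
        self.w = np.ones(n_levels)
        self.literal = literal_eq10

    def _change(self, tr: Trial) -> np.ndarray:
        n = self.n
        chg = np.zeros(n)
        rid = self.spec.rule_id
        if rid == 8:
            d = self.params["delta"]
            chg -= d / (n - 1)
            chg[tr.uv_value] = d
        elif rid == 9:
            dt, dd = self.params["delta_t"], self.params["delta_d"]
            chg -= dt / (n - 1)
            chg[tr.target_pos] = dt
            if self.literal:
                for k in tr.distractors:
                    chg -= -dd / 5.0  # printed form: every i != k gains dd/5
                    chg[k] += -dd / 3.0 - dd / 5.0
            else:
                is_d = np.zeros(n, dtype=bool)
                is_d[tr.distractors] = True
                chg[is_d] -= dd / 3.0
                chg[~is_d] += dd / 5.0
        elif rid == 10:
            d = self.params["delta"]
            chg[tr.target_pos] = d
            chg[tr.distractors] -= d / 3.0
        return chg

    def step(self, tr: Trial):
        scale = float(self.w[tr.uv_value])
        a = self.params["alpha"]
        self.w = a * (self.w + self._change(tr)) + (1.0 - a)
        return 0.0, scale, 0.0

    def state_vector(self):
        return self.w.copy()


class PositionWeightedRate(_RuleBase):
    """Rules 17/18: per-(level x position) weights for a binary UV.

    Rule 17 updates only the target position's weights (others just decay);
    rule 18 applies an omega**d gradient of the +/- delta update everywhere.
    """

    def __init__(self, spec, params, n_levels: int, validate: bool = True):
        super().__init__(spec, params, validate)
        self.n = n_levels
        self.w = np.ones((n_levels, N_POSITIONS))

    def step(self, tr: Trial):
        scale = float(self.w[tr.uv_value, tr.target_pos])
        a, d = self.params["alpha"], self.params["delta"]
        sign = -np.ones((self.n, 1))
        sign[tr.uv_value] = 1.0
        if self.spec.rule_id == 17:
            upd = np.zeros((self.n, N_POSITIONS))
            upd[:, tr.target_pos] = (sign * d)[:, 0]
        else:  # rule 18
            wd = self.params["omega"] ** _DIST[None, :, tr.target_pos]
            upd = sign * wd * d
        self.w = a * (self.w + upd) + (1.0 - a)
        return 0.0, scale, 0.0

    def state_vector(self):
        return np.ravel(self.w).copy()


class BinaryNDT(_RuleBase):
    """Rule 11: NDT shortened by delta when the UV repeats from n-1."""

    def step(self, tr: Trial):
        dndt = -self.params["delta"] if tr.rep else 0.0
        return 0.0, 1.0, dndt


class WeightedNDT(_RuleBase):
    """Rules 12/13/14: zero-sum NDT offsets over UV levels, decaying to 0."""

    def __init__(self, spec, params, n_levels: int, literal_eq13: bool = False,
                 validate: bool = True):
        super().__init__(spec, params, validate)
        self.n = n_levels
        self.dtau = np.zeros(n_levels)
        self.literal = literal_eq13

    def _change(self, tr: Trial) -> np.ndarray:
        n = self.n
        chg = np.zeros(n)
        rid = self.spec.rule_id
        if rid == 12:
            d = self.params["delta"]
            chg += d / (n - 1)
            chg[tr.uv_value] = -d
        elif rid == 13:
            dt, dd = self.params["delta_t"], self.params["delta_d"]
            chg += dt / (n - 1)
            chg[tr.target_pos] = -dt
            if self.literal:
                for k in tr.distractors:
                    chg += -dd / 5.0
                    chg[k] += dd / 3.0 + dd / 5.0
            else:
                is_d = np.zeros(n, dtype=bool)
                is_d[tr.distractors] = True
                chg[is_d] += dd / 3.0
                chg[~is_d] -= dd / 5.0
        elif rid == 14:
            d = self.params["delta"]
            chg[tr.target_pos] = -d
            chg[tr.distractors] += d / 3.0
        return chg

    def step(self, tr: Trial):
        dndt = float(self.dtau[tr.uv_value])
        self.dtau = self.params["alpha"] * (self.dtau + self._change(tr))
        return 0.0, 1.0, dndt

    def state_vector(self):
        return self.dtau.copy()


class PositionStepNDT(_RuleBase):
    """Rules 15/16: per-position NDT offsets driven by UV repetition.

    Repetition shortens the NDT at the (current) target position; a switch
    lengthens it. Rule 16 spreads the update over positions with an
    omega**d gradient. Update-then-apply, like the other step rules.
    """

    def __init__(self, spec, params, validate: bool = True):
        super().__init__(spec, params, validate)
        self.dtau = np.zeros(N_POSITIONS)

    def step(self, tr: Trial):
        a, d = self.params["alpha"], self.params["delta"]
        if tr.rep is not None:
            step = (-d) if tr.rep else d
            if self.spec.rule_id == 15:
                upd = np.zeros(N_POSITIONS)
                upd[tr.target_pos] = step
            else:  # rule 16
                upd = step * self.params["omega"] ** _DIST[:, tr.target_pos]
            self.dtau = a * (self.dtau + upd)
        else:
            self.dtau = a * self.dtau
        return 0.0, 1.0, float(self.dtau[tr.target_pos])

    def state_vector(self):
        return self.dtau.copy()


_UV_N_LEVELS = {"rcf": 2, "color": 2, "position": N_POSITIONS}


def make_rule(
    spec: RuleSpec,
    params: dict | None = None,
    grid_size: int = 101,
    literal_eq10: bool = False,
    _validate: bool = True,
) -> _RuleBase:
    """Instantiate a rule engine with fresh (session-start) state.

    Parameters are checked against the rule's declared box (e.g. the
    position-gradient omega must stay below 1; the binary-rate kappa must
    not exceed 1); ``_validate=False`` bypasses the check for limit studies.
    """
    params = params or {}
    n = _UV_N_LEVELS[spec.uv]
    rid = spec.rule_id
    if rid == 1:
        return NoUpdate(spec, params, _validate)
    if rid in (2, 3, 4, 5):
        return BayesS0(spec, params, grid_size=grid_size, validate=_validate)
    if rid == 6:
        return BinaryRate(spec, params, _validate)
    if rid == 7:
        return StepRate(spec, params, _validate)
    if rid in (8, 9, 10):
        return WeightedRate(spec, params, n_levels=n, literal_eq10=literal_eq10,
                            validate=_validate)
    if rid in (17, 18):
        return PositionWeightedRate(spec, params, n_levels=n, validate=_validate)
    if rid == 11:
        return BinaryNDT(spec, params, _validate)
    if rid in (12, 13, 14):
        return WeightedNDT(spec, params, n_levels=n, literal_eq13=literal_eq10,
                           validate=_validate)
    if rid in (15, 16):
        return PositionStepNDT(spec, params, _validate)
    raise ValueError(f"unknown rule id {rid}")


def _uv_values(arrays: SessionArrays, uv: str) -> np.ndarray:
    return {"rcf": arrays.notch, "color": arrays.color, "position": arrays.target_pos}[uv]


def run_rules(
    arrays: SessionArrays,
    active: Sequence[tuple[RuleSpec, dict]],
    grid_size: int = 101,
    snapshot_blocks: bool = False,
):
    """Single forward pass of all active rules over a session's stimuli.

    Returns per-trial arrays (delta_s0, rate_scale, delta_ndt); rate scales
    from different UVs multiply, starting-point and NDT offsets add. With
    ``snapshot_blocks`` also returns a dict {block -> state vector at the
    block's first trial} for state-continuity checks.
    """
    engines = [make_rule(spec, params, grid_size=grid_size) for spec, params in active]
    uv_vals = [_uv_values(arrays, spec.uv) for spec, _ in active]
    n = arrays.n
    ds0 = np.zeros(n)
    scale = np.ones(n)
    dndt = np.zeros(n)
    snapshots: dict[int, np.ndarray] = {}
    for i in range(n):
        if snapshot_blocks and (i == 0 or arrays.block[i] != arrays.block[i - 1]):
            parts = [eng.state_vector() for eng in engines]
            snapshots[int(arrays.block[i])] = (
                np.concatenate(parts) if parts else np.zeros(0)
            )
        for eng, vals in zip(engines, uv_vals):
            rep = None if i == 0 else bool(vals[i] == vals[i - 1])
            tr = Trial(
                uv_value=int(vals[i]),
                rep=rep,
                target_pos=int(arrays.target_pos[i]),
                distractors=arrays.distractors[i],
            )
            a, b, c = eng.step(tr)
            ds0[i] += a
            scale[i] *= b
            dndt[i] += c
    if snapshot_blocks:
        return ds0, scale, dndt, snapshots
    return ds0, scale, dndt
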