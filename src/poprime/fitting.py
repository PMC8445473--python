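"""Maximum-likelihood fitting of updating models to session RT data.

The likelihood is a single forward pass over a session in trial order: the
active updating rules produce a per-trial modulation (starting-point shift,
rate scale, NDT offset) of the evidence-accumulation model, and each trial
that is correct and inside the RT window [0.2 s, 1.5 s] contributes
-log f(rt) for the corresponding (LATER or DDM correct-boundary) density.
Error trials and outliers are excluded from the likelihood but still
advance the rule states.

Optimization is nested, mirroring the inner/outer structure of the model:
the *outer* derivative-free simplex searches the non-decision time plus the
0-3 parameters of each updating rule (through a logistic transform to the
parameter box); for every outer point, the *inner* bounded quasi-Newton
optimization finds the best four parameters of the evidence-accumulation
model itself. Because rule states depend only on the stimulus sequence and
the outer parameters, the per-trial modulations are computed once per outer
point and the inner objective is fully vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from . import rules as rules_mod
from .ea import DDMParams, LATERParams, _wfpt_lower
from .paradigm import SessionArrays, SessionData, session_to_arrays
from .rules import RuleSpec, registry_levels, run_rules

__all__ = [
    "ModelSpec",
    "FitConfig",
    "FitResult",
    "session_negloglik",
    "fit_inner",
    "fit_model",
    "no_update_spec",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)
_START_EPS = 1e-3

_INNER_NAMES = {
    "LATER": ("theta", "s0_base", "mu_r", "sigma_r"),
    "DDM": ("theta", "s0_base", "r", "s"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the factorial design: an EA model and one rule per UV."""

    ea_model: str  # 'LATER' | 'DDM'
    rcf_rule: RuleSpec
    color_rule: RuleSpec
    position_rule: RuleSpec

    def __post_init__(self):
        if self.ea_model not in ("LATER", "DDM"):
            raise ValueError(f"unknown EA model {self.ea_model!r}")
        for uv, rule in (
            ("rcf", self.rcf_rule),
            ("color", self.color_rule),
            ("position", self.position_rule),
        ):
            if rule.uv != uv:
                raise ValueError(f"rule {rule.key} used for the {uv} factor")

    @property
    def rules(self) -> tuple[RuleSpec, RuleSpec, RuleSpec]:
        return (self.rcf_rule, self.color_rule, self.position_rule)

    @property
    def n_rule_params(self) -> int:
        return sum(r.n_params for r in self.rules)

    @property
    def n_free_parameters(self) -> int:
        # 4 inner EA parameters + the non-decision time + rule parameters
        return 4 + 1 + self.n_rule_params

    @property
    def key(self) -> str:
        return (
            f"{self.ea_model}|{self.rcf_rule.name}|"
            f"{self.color_rule.name}|{self.position_rule.name}"
        )


def no_update_spec(ea_model: str = "LATER") -> ModelSpec:
    return ModelSpec(
        ea_model,
        rules_mod.NO_UPDATE["rcf"],
        rules_mod.NO_UPDATE["color"],
        rules_mod.NO_UPDATE["position"],
    )


@dataclass(frozen=True)
class FitConfig:
    """Exclusion window, parameter boxes and optimizer budgets."""

    rt_lower: float = 0.2
    rt_upper: float = 1.5
    tau_bounds: tuple[float, float] = (0.05, 0.45)
    inner_bounds_later: tuple = (
        ("theta", (0.2, 8.0)),
        ("s0_base", (-2.0, 2.0)),
        ("mu_r", (0.5, 25.0)),
        ("sigma_r", (0.1, 10.0)),
    )
    inner_bounds_ddm: tuple = (
        ("theta", (0.5, 8.0)),
        ("s0_base", (-3.0, 3.0)),
        ("r", (0.5, 25.0)),
        ("s", (0.2, 6.0)),
    )
    inner_restarts: int = 3
    inner_maxiter: int = 200
    outer_restarts: int = 2
    outer_maxfev_per_dim: int = 60
    outer_fatol: float = 0.05
    grid_size: int = 101
    density_floor_nll: float = 50.0  # per-trial penalty for non-finite densities
    seed: int = 0

    def inner_bounds(self, ea_model: str) -> dict[str, tuple[float, float]]:
        pairs = self.inner_bounds_later if ea_model == "LATER" else self.inner_bounds_ddm
        return dict(pairs)

    def __post_init__(self):
        if not self.rt_lower < self.rt_upper:
            raise ValueError("rt_lower must be below rt_upper")


@dataclass
class FitResult:
    model: ModelSpec
    inner_params: dict[str, float]
    tau: float
    rule_params: dict[str, dict[str, float]]  # uv -> {name: value}
    loglik: float
    n_free_parameters: int
    aic: float
    converged: bool
    n_valid_trials: int

    def to_dict(self) -> dict:
        return {
            "model": self.model.key,
            "inner_params": self.inner_params,
            "tau": self.tau,
            "rule_params": self.rule_params,
            "loglik": self.loglik,
            "n_free_parameters": self.n_free_parameters,
            "aic": self.aic,
            "converged": self.converged,
            "n_valid_trials": self.n_valid_trials,
        }


# ---------------------------------------------------------------------------
# Likelihood


def _as_arrays(session) -> SessionArrays:
    return session if isinstance(session, SessionArrays) else session_to_arrays(session)


def valid_mask(arrays: SessionArrays, config: FitConfig) -> np.ndarray:
    """Trials that contribute likelihood terms: correct and inside the window."""
    rt = arrays.rt
    with np.errstate(invalid="ignore"):
        ok = (rt >= config.rt_lower) & (rt <= config.rt_upper)
    return arrays.correct & np.nan_to_num(ok, nan=False)


def _active_rules(spec: ModelSpec, rule_params: dict) -> list[tuple[RuleSpec, dict]]:
    out = []
    for rule in spec.rules:
        if rule.rule_id != 1:
            out.append((rule, rule_params.get(rule.uv, {})))
    return out


def _modulations(arrays, spec: ModelSpec, rule_params: dict, config: FitConfig):
    return run_rules(arrays, _active_rules(spec, rule_params), grid_size=config.grid_size)


def _nll_terms_later(rt, ds0, scale, dndt, theta, s0, mu, sigma, tau, floor):
    d = theta - (s0 + ds0)
    d = np.maximum(d, _START_EPS * theta)  # keep the geometry non-degenerate
    tau_eff = np.maximum(tau + dndt, 0.0)
    dt = rt - tau_eff
    m = scale * mu
    out = np.full(rt.shape, floor)
    ok = dt > 0
    if np.any(ok):
        z = (d[ok] / dt[ok] - m[ok]) / sigma
        logf = (
            np.log(d[ok])
            - 2.0 * np.log(dt[ok])
            - 0.5 * z**2
            - np.log(_SQRT_2PI * sigma)
            - stats.norm.logcdf(m[ok] / sigma)
        )
        out[ok] = np.minimum(-logf, floor)
    return out


def _nll_terms_ddm(rt, ds0, scale, dndt, theta, s0, r, s, tau, floor):
    z = np.clip(theta / 2.0 + s0 + ds0, _START_EPS * theta, (1.0 - _START_EPS) * theta)
    tau_eff = np.maximum(tau + dndt, 0.0)
    td = rt - tau_eff
    a = theta / s
    v = scale * r / s
    w = z / theta
    f = _wfpt_lower(td, -v, a, 1.0 - w)  # correct (upper) boundary
    with np.errstate(divide="ignore"):
        return np.minimum(-np.log(f), floor)


def _nll_from_mods(arrays, spec, inner, tau, mods, valid, config) -> float:
    ds0, scale, dndt = mods
    rt = arrays.rt[valid]
    if rt.size == 0:
        return 0.0
    args = (rt, ds0[valid], scale[valid], dndt[valid])
    floor = config.density_floor_nll
    if spec.ea_model == "LATER":
        terms = _nll_terms_later(
            *args, inner["theta"], inner["s0_base"], inner["mu_r"], inner["sigma_r"], tau, floor
        )
    else:
        terms = _nll_terms_ddm(
            *args, inner["theta"], inner["s0_base"], inner["r"], inner["s"], tau, floor
        )
    return float(np.sum(terms))


def session_negloglik(session, model_spec: ModelSpec, params: dict, config=None) -> float:
    """Negative log-likelihood of one session under one model.

    ``params`` holds the inner EA parameters by name, ``'tau'``, and
    ``'rules'``: a dict mapping uv -> rule parameter dict.
    """
    config = config or FitConfig()
    arrays = _as_arrays(session)
    rule_params = params.get("rules", {})
    mods = _modulations(arrays, model_spec, rule_params, config)
    valid = valid_mask(arrays, config)
    inner = {k: params[k] for k in _INNER_NAMES[model_spec.ea_model]}
    return _nll_from_mods(arrays, model_spec, inner, params["tau"], mods, valid, config)


# ---------------------------------------------------------------------------
# Inner optimization (EA parameters, vectorized given fixed modulations)


def _inner_starts(arrays, ea_model, tau, valid, bounds, rng, n_extra):
    rt = arrays.rt[valid]
    starts = []
    if ea_model == "LATER":
        dt = np.maximum(rt - tau, 1e-3)
        recip = 1.0 / dt
        mu0 = float(np.clip(np.mean(recip), *bounds["mu_r"]))
        sg0 = float(np.clip(np.std(recip) + 1e-3, *bounds["sigma_r"]))
        starts.append([1.0, 0.0, mu0, sg0])
    else:
        starts.append([2.0, 0.0, 6.0, 2.0])
    names = _INNER_NAMES[ea_model]
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    base = np.array(starts[0])
    for _ in range(n_extra):
        jitter = base * np.exp(rng.normal(0.0, 0.25, size=4))
        starts.append(list(np.clip(jitter, lo, hi)))
    return starts, list(zip(lo, hi))


def _fit_inner_multi(arrays_list, model_spec, tau, mods_list, valids, config):
    """Shared inner EA parameters over one or more sessions (vectorized)."""
    names = _INNER_NAMES[model_spec.ea_model]
    bounds = config.inner_bounds(model_spec.ea_model)
    rng = np.random.default_rng(config.seed)
    starts, box = _inner_starts(
        arrays_list[0], model_spec.ea_model, tau, valids[0], bounds, rng,
        config.inner_restarts - 1,
    )

    def objective(x):
        inner = dict(zip(names, x))
        return sum(
            _nll_from_mods(arr, model_spec, inner, tau, mods, v, config)
            for arr, mods, v in zip(arrays_list, mods_list, valids)
        )

    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=box,
            options={"maxiter": config.inner_maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    return dict(zip(names, best.x)), float(best.fun), converged


def fit_inner(
    session,
    model_spec: ModelSpec,
    outer_params: dict,
    config: FitConfig | None = None,
    _mods=None,
    _valid=None,
):
    """Optimize the 4 EA parameters at fixed outer (tau + rule) parameters.

    Returns (inner parameter dict, negative log-likelihood, converged flag).
    """
    config = config or FitConfig()
    arrays = _as_arrays(session)
    tau = float(outer_params["tau"])
    if _mods is None:
        _mods = _modulations(arrays, model_spec, outer_params.get("rules", {}), config)
    if _valid is None:
        _valid = valid_mask(arrays, config)
    return _fit_inner_multi([arrays], model_spec, tau, [_mods], [_valid], config)


# ---------------------------------------------------------------------------
# Outer optimization (tau + rule parameters)


def _outer_layout(spec: ModelSpec, config: FitConfig):
    """Names, boxes and default starts of the outer parameter vector."""
    names: list[tuple[str, str]] = [("tau", "tau")]
    boxes = [config.tau_bounds]
    defaults = {"alpha": 0.8, "beta0": 2.0, "omega": 0.5, "sigma_spread": 1.0, "kappa": 0.8}
    x0 = [0.3]
    for rule in spec.rules:
        for pname, pb in zip(rule.param_names, rule.param_bounds):
            names.append((rule.uv, pname))
            boxes.append(pb)
            if pname in defaults:
                x0.append(float(np.clip(defaults[pname], *pb)))
            elif pname.startswith("delta"):
                x0.append(pb[0] + 0.25 * (pb[1] - pb[0]))
            else:
                x0.append(0.5 * (pb[0] + pb[1]))
    return names, np.array(boxes, dtype=float), np.array(x0, dtype=float)


def _to_unbounded(x, boxes):
    u = (x - boxes[:, 0]) / (boxes[:, 1] - boxes[:, 0])
    u = np.clip(u, 1e-6, 1.0 - 1e-6)
    return np.log(u / (1.0 - u))


def _from_unbounded(y, boxes):
    u = 1.0 / (1.0 + np.exp(-y))
    return boxes[:, 0] + u * (boxes[:, 1] - boxes[:, 0])


def _unpack_outer(x, names):
    tau = float(x[0])
    rule_params: dict[str, dict[str, float]] = {}
    for (uv, pname), val in zip(names[1:], x[1:]):
        rule_params.setdefault(uv, {})[pname] = float(val)
    return tau, rule_params


def fit_model(
    sessions,
    model_spec: ModelSpec,
    config: FitConfig | None = None,
    exclude_block: int | None = None,
) -> FitResult:
    """Full nested maximum-likelihood fit; AIC per the counting contract.

    ``sessions`` may be one session or a list fitted jointly (rule states
    reset at each session start). ``exclude_block`` drops one block's trials
    from the likelihood (their stimuli still drive the rule states), which
    is the training step of the block-wise cross-validation.
    """
    config = config or FitConfig()
    if isinstance(sessions, (SessionData, SessionArrays)):
        sessions = [sessions]
    arrays_list = [_as_arrays(s) for s in sessions]
    valids = []
    for arr in arrays_list:
        v = valid_mask(arr, config)
        if exclude_block is not None:
            v = v & (arr.block != exclude_block)
        valids.append(v)
    names, boxes, x0 = _outer_layout(model_spec, config)
    rng = np.random.default_rng(config.seed + 1)

    def outer_objective(y):
        x = _from_unbounded(y, boxes)
        tau, rule_params = _unpack_outer(x, names)
        mods_list = [
            _modulations(arr, model_spec, rule_params, config) for arr in arrays_list
        ]
        _, nll, _ = _fit_inner_multi(arrays_list, model_spec, tau, mods_list, valids, config)
        return nll

    dim = len(x0)
    maxfev = config.outer_maxfev_per_dim * dim
    starts = [x0]
    for _ in range(config.outer_restarts - 1):
        jit = x0 + rng.normal(0.0, 0.15, size=dim) * (boxes[:, 1] - boxes[:, 0])
        starts.append(np.clip(jit, boxes[:, 0] + 1e-9, boxes[:, 1] - 1e-9))

    best = None
    converged = False
    for s0 in starts:
        res = optimize.minimize(
            outer_objective,
            _to_unbounded(s0, boxes),
            method="Nelder-Mead",
            options={"maxfev": maxfev, "fatol": config.outer_fatol, "xatol": 1e-3},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    x_best = _from_unbounded(best.x, boxes)
    tau, rule_params = _unpack_outer(x_best, names)
    # final inner fit at the best outer point
    mods_list = [_modulations(arr, model_spec, rule_params, config) for arr in arrays_list]
    inner_final, total_nll, _ = _fit_inner_multi(
        arrays_list, model_spec, tau, mods_list, valids, config
    )
    n_valid = int(sum(np.sum(v) for v in valids))
    loglik = -total_nll
    k = model_spec.n_free_parameters
    return FitResult(
        model=model_spec,
        inner_params=inner_final,
        tau=tau,
        rule_params=rule_params,
        loglik=loglik,
        n_free_parameters=k,
        aic=2.0 * k - 2.0 * loglik,
        converged=converged,
        n_valid_trials=n_valid,
    )
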