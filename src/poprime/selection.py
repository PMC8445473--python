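"""Factorial model comparison by AIC and block-wise cross-validation.

The model space is a 2 x 12 x 8 x 10 factorial (evidence-accumulation
model x RCF rule x color rule x position rule; 1920 cells). Exhaustively
fitting every cell to every participant-session is supported for toy
problems; the default is the coordinate search the analysis pipeline uses:
each updating-rule factor is swept with the other two fixed (first to
no-update, in later rounds to the current best), across the EA-model
levels, and rounds repeat until no factor's best level changes.

Relative AIC subtracts the overall winning model's AIC per participant-
session before averaging, so the winner sits at exactly zero and the other
entries say how much worse they are.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import (
    FitConfig,
    FitResult,
    ModelSpec,
    _as_arrays,
    _modulations,
    _nll_from_mods,
    fit_model,
    valid_mask,
)
from .paradigm import SessionData
from .rules import RuleSpec, registry_levels

__all__ = [
    "aic",
    "relative_aic",
    "enumerate_model_specs",
    "SearchConfig",
    "CoordinateSearchResult",
    "coordinate_search",
    "exhaustive_comparison",
    "cross_validate",
]

_UV_ATTR = {"rcf": "rcf_rule", "color": "color_rule", "position": "position_rule"}


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 log L (lower is better)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return 2.0 * k - 2.0 * loglik


def relative_aic(table: pd.DataFrame) -> pd.DataFrame:
    """Per-model mean relative AIC (winner = 0) with SEM.

    ``table`` has one row per (participant, session, model) with an 'aic'
    column; every participant-session must cover every model.
    """
    required = {"participant", "session", "model", "aic"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    counts = table.groupby("model").size()
    if counts.nunique() > 1:
        raise ValueError("incomplete table: models fitted to different session sets")
    winner = table.groupby("model")["aic"].mean().idxmin()
    wide = table.pivot_table(index=["participant", "session"], columns="model", values="aic")
    if wide.isna().any().any():
        raise ValueError("incomplete table: missing (participant, session, model) cells")
    rel = wide.sub(wide[winner], axis=0)
    out = pd.DataFrame(
        {
            "mean_relative_aic": rel.mean(axis=0),
            "sem": rel.std(axis=0, ddof=1) / np.sqrt(len(rel)) if len(rel) > 1 else np.nan,
        }
    )
    out.index.name = "model"
    return out.reset_index()


def enumerate_model_specs(
    ea_levels=("LATER", "DDM"),
    rcf_levels=None,
    color_levels=None,
    position_levels=None,
) -> list[ModelSpec]:
    """All cells of the factorial design (1920 with the full registry)."""
    rcf_levels = rcf_levels if rcf_levels is not None else registry_levels("rcf")
    color_levels = color_levels if color_levels is not None else registry_levels("color")
    position_levels = (
        position_levels if position_levels is not None else registry_levels("position")
    )
    return [
        ModelSpec(ea, r, c, p)
        for ea, r, c, p in itertools.product(
            ea_levels, rcf_levels, color_levels, position_levels
        )
    ]


@dataclass
class SearchConfig:
    """Scope and budgets of the coordinate search."""

    fit_config: FitConfig = field(default_factory=FitConfig)
    ea_levels: tuple[str, ...] = ("LATER", "DDM")
    rcf_levels: list[RuleSpec] | None = None
    color_levels: list[RuleSpec] | None = None
    position_levels: list[RuleSpec] | None = None
    max_rounds: int = 6

    def levels(self, uv: str) -> list[RuleSpec]:
        chosen = {"rcf": self.rcf_levels, "color": self.color_levels,
                  "position": self.position_levels}[uv]
        return list(chosen) if chosen is not None else registry_levels(uv)


@dataclass
class CoordinateSearchResult:
    winner: ModelSpec
    converged: bool
    n_rounds: int
    n_fits: int
    audit: list[dict]  # per round: {uv: ComparisonTable DataFrame}
    table: pd.DataFrame  # all fits performed (tidy)


def _session_meta(sessions) -> list[tuple[str, str, object]]:
    return [(s.participant, s.session, s) for s in sessions]


def coordinate_search(sessions, config: SearchConfig | None = None) -> CoordinateSearchResult:
    """Coordinate-wise factorial search for the best rule combination.

    Round 1 sweeps each updating-rule factor with the other two fixed to
    no-update; later rounds fix them to the current best levels. The best
    level of a factor minimizes the mean AIC across participants, sessions
    and EA-model levels (ties broken toward fewer parameters, then registry
    order). The search stops when a full round changes nothing; the final
    EA model is the level with the lower mean AIC at the winning rule
    combination.
    """
    config = config or SearchConfig()
    if isinstance(sessions, SessionData):
        sessions = [sessions]
    meta = _session_meta(sessions)
    uvs = ("rcf", "color", "position")
    current = {uv: config.levels(uv)[0] for uv in uvs}  # registry order puts no-update first
    cache: dict[tuple, FitResult] = {}
    rows: list[dict] = []

    def fit_cell(spec: ModelSpec, pid, sid, sess) -> FitResult:
        key = (pid, sid, spec.key)
        if key not in cache:
            cache[key] = fit_model(sess, spec, config.fit_config)
            rows.append(
                {
                    "participant": pid,
                    "session": sid,
                    "model": spec.key,
                    "ea_model": spec.ea_model,
                    "rcf": spec.rcf_rule.name,
                    "color": spec.color_rule.name,
                    "position": spec.position_rule.name,
                    "loglik": cache[key].loglik,
                    "k": cache[key].n_free_parameters,
                    "aic": cache[key].aic,
                }
            )
        return cache[key]

    audit = []
    converged = False
    n_rounds = 0
    for _ in range(config.max_rounds):
        n_rounds += 1
        previous = dict(current)
        round_tables = {}
        for uv in uvs:
            level_aics = []
            for level in config.levels(uv):
                fills = {**current, uv: level}
                aics = []
                for ea in config.ea_levels:
                    spec = ModelSpec(ea, fills["rcf"], fills["color"], fills["position"])
                    for pid, sid, sess in meta:
                        aics.append(fit_cell(spec, pid, sid, sess).aic)
                level_aics.append((float(np.mean(aics)), level.n_params, level))
            # min AIC; ties toward fewer parameters, then registry order
            best = min(
                range(len(level_aics)),
                key=lambda i: (round(level_aics[i][0], 10), level_aics[i][1], i),
            )
            current[uv] = level_aics[best][2]
            round_tables[uv] = pd.DataFrame(
                {
                    "level": [t[2].name for t in level_aics],
                    "mean_aic": [t[0] for t in level_aics],
                }
            )
        audit.append(round_tables)
        if all(current[uv].name == previous[uv].name for uv in uvs):
            converged = True
            break

    # pick the EA model at the winning combination
    ea_means = []
    for ea in config.ea_levels:
        spec = ModelSpec(ea, current["rcf"], current["color"], current["position"])
        ea_means.append(
            (np.mean([fit_cell(spec, pid, sid, sess).aic for pid, sid, sess in meta]), ea)
        )
    best_ea = min(ea_means)[1]
    winner = ModelSpec(best_ea, current["rcf"], current["color"], current["position"])
    return CoordinateSearchResult(
        winner=winner,
        converged=converged,
        n_rounds=n_rounds,
        n_fits=len(cache),
        audit=audit,
        table=pd.DataFrame(rows),
    )


def exhaustive_comparison(sessions, specs: list[ModelSpec], config: FitConfig | None = None):
    """Fit every listed model to every session; returns the tidy AIC table."""
    config = config or FitConfig()
    if isinstance(sessions, SessionData):
        sessions = [sessions]
    rows = []
    for spec in specs:
        for s in sessions:
            res = fit_model(s, spec, config)
            rows.append(
                {
                    "participant": s.participant,
                    "session": s.session,
                    "model": spec.key,
                    "loglik": res.loglik,
                    "k": res.n_free_parameters,
                    "aic": res.aic,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Block-wise cross-validation


def _block_logliks(arrays, spec, fit: FitResult, config) -> dict[int, float]:
    """Log-likelihood per block at the fitted parameters (full-session pass)."""
    mods = _modulations(arrays, spec, fit.rule_params, config)
    valid = valid_mask(arrays, config)
    out = {}
    for b in np.unique(arrays.block):
        sel = valid & (arrays.block == b)
        out[int(b)] = -_nll_from_mods(arrays, spec, fit.inner_params, fit.tau, mods, sel, config)
    return out


def cross_validate(
    session, model_spec: ModelSpec, config: FitConfig | None = None, n_folds: int = 8
) -> dict:
    """Eight-fold block-wise cross-validation of one model on one session.

    For each fold, the model is fitted on the other blocks' likelihood
    terms while the stimulus sequence of the held-out block still drives
    the rule states (so state continuity across the train/test boundary is
    preserved); the held-out block's log-likelihood is then evaluated at
    the fitted parameters. The training summary averages each block's
    log-likelihood over the folds in which it was a training block and sums
    over blocks, putting it on the same 8-block scale as the test sum.
    """
    config = config or FitConfig()
    arrays = _as_arrays(session)
    blocks = sorted(int(b) for b in np.unique(arrays.block))
    if len(blocks) != n_folds:
        raise ValueError(f"session has {len(blocks)} blocks, expected {n_folds} folds")
    train_ll: dict[int, list[float]] = {b: [] for b in blocks}
    test_ll: dict[int, float] = {}
    fold_fits = {}
    for held_out in blocks:
        fit = fit_model(arrays, model_spec, config, exclude_block=held_out)
        per_block = _block_logliks(arrays, model_spec, fit, config)
        test_ll[held_out] = per_block[held_out]
        for b in blocks:
            if b != held_out:
                train_ll[b].append(per_block[b])
        fold_fits[held_out] = fit
    train_total = float(sum(np.mean(train_ll[b]) for b in blocks))
    test_total = float(sum(test_ll.values()))
    return {
        "train_loglik": train_total,
        "test_loglik": test_total,
        "per_block_test": test_ll,
        "fold_fits": fold_fits,
    }
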