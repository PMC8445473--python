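"""n-back temporal profiles of normalized RTs, for data and model.

A lag-k inter-trial effect is the difference in normalized RT (RT minus
the participant-session mean over valid trials) between conditions defined
by the transition from trial n-k to trial n: color repeat vs. switch,
positional TT/TN/TD, or RCF repeat/switch crossed with the positional
transition. Normalized RTs are first averaged within participant (pooling
sessions), then across participants with normal-approximation 95% CIs.

Model profiles replace each valid trial's RT with the expected RT of the
fitted evidence-accumulation model under that trial's modulation,
restricted to the analysis window, minus the session's observed mean RT —
so data and model rows aggregate over exactly the same trials.

Lag-k pairs are unconditional (intermediate trials are not constrained)
and may span block boundaries within a session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .ea import _wfpt_lower
from .fitting import FitConfig, FitResult, ModelSpec, _as_arrays, _modulations, valid_mask
from .paradigm import SessionData

__all__ = ["normalize_rts", "nback_profile", "model_predicted_profile", "plot_profile"]

_SQRT_2PI = np.sqrt(2.0 * np.pi)
_START_EPS = 1e-3

_VARIABLES = ("color", "position", "rcf_by_position")


def normalize_rts(session, config: FitConfig | None = None) -> pd.Series:
    """RT minus the session's mean RT, over valid trials only.

    Indexed by the trial's 0-based position in the session; the mean of the
    output is exactly zero. Sessions are normalized independently.
    """
    config = config or FitConfig()
    arrays = _as_arrays(session)
    valid = valid_mask(arrays, config)
    if not np.any(valid):
        raise ValueError("session has no valid trials to normalize")
    rt = arrays.rt[valid]
    return pd.Series(rt - rt.mean(), index=np.nonzero(valid)[0])


def _condition_labels(arrays, lag: int, variable: str) -> np.ndarray:
    """Transition condition of each trial n relative to trial n - lag."""
    n = arrays.n
    labels = np.full(n, "", dtype=object)
    cur = slice(lag, n)
    prev = slice(0, n - lag)
    tpos_c, tpos_p = arrays.target_pos[cur], arrays.target_pos[prev]
    tt = tpos_c == tpos_p
    td = (arrays.distractors[prev] == tpos_c[:, None]).any(axis=1)
    pos_label = np.where(tt, "TT", np.where(td, "TD", "TN"))
    if variable == "color":
        rep = arrays.color[cur] == arrays.color[prev]
        labels[cur] = np.where(rep, "repeat", "switch")
    elif variable == "position":
        labels[cur] = pos_label
    elif variable == "rcf_by_position":
        rep = arrays.notch[cur] == arrays.notch[prev]
        labels[cur] = np.char.add(
            np.where(rep, "repeat:", "switch:").astype(str), pos_label.astype(str)
        )
    else:
        raise ValueError(f"unknown profile variable {variable!r} (one of {_VARIABLES})")
    return labels


def _profile_from_values(
    sessions, values_per_session, variable: str, max_lag: int, source: str
) -> pd.DataFrame:
    """Aggregate per-trial values into the lag x condition profile table."""
    rows = []
    for session, vals in zip(sessions, values_per_session):
        arrays = _as_arrays(session)
        if arrays.n <= max_lag:
            raise ValueError(f"session shorter than max_lag + 1 = {max_lag + 1} trials")
        idx = vals.index.to_numpy()
        for lag in range(1, max_lag + 1):
            labels = _condition_labels(arrays, lag, variable)
            usable = idx[idx >= lag]
            for i in usable:
                rows.append(
                    {
                        "participant": session.participant,
                        "lag": lag,
                        "condition": labels[i],
                        "value": vals.loc[i],
                    }
                )
    long = pd.DataFrame(rows)
    # within participant first (pooling sessions), then across participants
    per_part = (
        long.groupby(["participant", "lag", "condition"])["value"].mean().reset_index()
    )
    n_trials = long.groupby(["lag", "condition"]).size().rename("n_trials")

    def agg(g):
        m = g["value"].mean()
        k = len(g)
        ci = 1.96 * g["value"].std(ddof=1) / np.sqrt(k) if k > 1 else np.nan
        return pd.Series({"mean_nrt": m, "ci_halfwidth": ci})

    out = (
        per_part.groupby(["lag", "condition"])
        .apply(agg, include_groups=False)
        .reset_index()
        .merge(n_trials.reset_index(), on=["lag", "condition"])
    )
    out["source"] = source
    return out


def nback_profile(sessions, variable: str, max_lag: int = 8,
                  config: FitConfig | None = None) -> pd.DataFrame:
    """Observed mean normalized RT per lag (1..max_lag) and condition."""
    config = config or FitConfig()
    if isinstance(sessions, SessionData):
        sessions = [sessions]
    values = [normalize_rts(s, config) for s in sessions]
    return _profile_from_values(sessions, values, variable, max_lag, source="data")


def _expected_rts(arrays, spec: ModelSpec, fit: FitResult, valid, config) -> np.ndarray:
    """Window-restricted expected RT per valid trial, vectorized over trials."""
    ds0, scale, dndt = _modulations(arrays, spec, fit.rule_params, config)
    ds0, scale, dndt = ds0[valid], scale[valid], dndt[valid]
    p = fit.inner_params
    tau_eff = np.maximum(fit.tau + dndt, 0.0)[:, None]
    t = np.linspace(config.rt_lower, config.rt_upper, 400)[None, :]
    if spec.ea_model == "LATER":
        d = np.maximum(p["theta"] - (p["s0_base"] + ds0), _START_EPS * p["theta"])[:, None]
        mu = (scale * p["mu_r"])[:, None]
        sig = p["sigma_r"]
        dt = t - tau_eff
        f = np.zeros_like(dt)
        ok = dt > 0
        r = np.where(ok, d / np.where(ok, dt, 1.0), 0.0)
        f = np.where(
            ok,
            (d / np.where(ok, dt, 1.0) ** 2)
            * np.exp(-0.5 * ((r - mu) / sig) ** 2)
            / (_SQRT_2PI * sig * stats.norm.cdf(mu / sig)),
            0.0,
        )
    else:
        theta, s = p["theta"], p["s"]
        z = np.clip(
            theta / 2.0 + p["s0_base"] + ds0, _START_EPS * theta, (1.0 - _START_EPS) * theta
        )
        w = (z / theta)[:, None]
        v = (scale * p["r"] / s)[:, None]
        f = _wfpt_lower(t - tau_eff, -v, theta / s, 1.0 - w)
    mass = integrate.trapezoid(f, t[0], axis=1)
    mean = integrate.trapezoid(f * t, t[0], axis=1)
    if np.any(mass <= 0):
        raise ValueError("a trial's predicted density has no mass in the window")
    return mean / mass


def model_predicted_profile(
    sessions,
    fits,
    variable: str,
    max_lag: int = 8,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Model-predicted profile, aggregated exactly like :func:`nback_profile`.

    ``fits`` is one FitResult (shared) or a list parallel to ``sessions``.
    Each valid trial contributes the model's expected RT under that trial's
    modulation minus the session's observed mean RT.
    """
    config = config or FitConfig()
    if isinstance(sessions, SessionData):
        sessions = [sessions]
    if isinstance(fits, FitResult):
        fits = [fits] * len(sessions)
    values = []
    for session, fit in zip(sessions, fits):
        arrays = _as_arrays(session)
        valid = valid_mask(arrays, config)
        pred = _expected_rts(arrays, fit.model, fit, valid, config)
        obs_mean = arrays.rt[valid].mean()
        values.append(pd.Series(pred - obs_mean, index=np.nonzero(valid)[0]))
    return _profile_from_values(sessions, values, variable, max_lag, source="model")


def plot_profile(data: pd.DataFrame, model: pd.DataFrame | None = None, ax=None):
    """Plot a profile table: points with CI bars for data, lines for model.

    Both tables come from :func:`nback_profile` / :func:`model_predicted_profile`.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for i, (cond, g) in enumerate(data.groupby("condition")):
        color = f"C{i}"
        ax.errorbar(
            g["lag"], g["mean_nrt"], yerr=g["ci_halfwidth"],
            fmt="o", color=color, label=str(cond), capsize=2,
        )
        if model is not None:
            gm = model[model.condition == cond]
            ax.plot(gm["lag"], gm["mean_nrt"], "-", color=color)
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("lag (trials back)")
    ax.set_ylabel("normalized RT (s)")
    ax.legend(title="condition")
    return ax
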