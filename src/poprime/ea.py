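"""Single-trial evidence-accumulation models: LATER and the drift-diffusion model.

Both models describe one perceptual decision per search trial. The LATER
model accumulates evidence linearly at a rate drawn once per trial from a
normal distribution (truncated to positive rates here, so the density is
proper); RT = non-decision time + distance-to-threshold / rate. The DDM is
a Wiener process with drift between two absorbing boundaries; the boundary
hit determines the response, and we use the exact first-passage-time
density (small-time / large-time series with automatic switching).

Trial history enters through a :class:`TrialModulation`: an additive
starting-point shift ``delta_s0`` (signed toward the current trial's correct
boundary, interpreted as log prior odds), a multiplicative rate scale, and
an additive non-decision-time offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "LATERParams",
    "DDMParams",
    "TrialModulation",
    "IDENTITY_MODULATION",
    "later_density",
    "ddm_fpt_density",
    "ddm_upper_probability",
    "sample",
    "expected_rt",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)

# relative clamp keeping the DDM start strictly inside (0, theta)
_START_EPS = 1e-3


@dataclass(frozen=True)
class LATERParams:
    """LATER: rate r ~ N(mu_r, sigma_r) truncated to r > 0, RT = tau + D / r
    with D = theta - s0."""

    theta: float  # boundary (evidence units)
    s0_base: float  # baseline starting level (log-odds scale)
    mu_r: float  # mean rate (evidence / s)
    sigma_r: float  # across-trial SD of the rate
    tau: float  # baseline non-decision time (s)

    def validate(self) -> None:
        if not self.theta > self.s0_base:
            raise ValueError("theta must exceed s0_base (positive distance to threshold)")
        if self.mu_r <= 0 or self.sigma_r <= 0:
            raise ValueError("mu_r and sigma_r must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")


@dataclass(frozen=True)
class DDMParams:
    """Wiener diffusion between boundaries {0, theta}, start theta/2 + s0."""

    theta: float  # boundary separation
    s0_base: float  # starting-point offset from the midpoint (log-odds units)
    r: float  # drift rate toward the correct (upper) boundary
    s: float  # diffusion scaling parameter
    tau: float  # baseline non-decision time (s)

    def validate(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.s <= 0:
            raise ValueError("diffusion scale s must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")


@dataclass(frozen=True)
class TrialModulation:
    """Per-trial parameter deltas contributed by the active updating rules.

    Composition identity is (0, 1, 0). Rates from different rules multiply;
    starting-point shifts and NDT offsets add.
    """

    delta_s0: float = 0.0
    rate_scale: float = 1.0
    delta_ndt: float = 0.0

    def compose(self, other: "TrialModulation") -> "TrialModulation":
        return TrialModulation(
            delta_s0=self.delta_s0 + other.delta_s0,
            rate_scale=self.rate_scale * other.rate_scale,
            delta_ndt=self.delta_ndt + other.delta_ndt,
        )


IDENTITY_MODULATION = TrialModulation()


# ---------------------------------------------------------------------------
# LATER


def _later_geometry(p: LATERParams, m: TrialModulation):
    d = p.theta - (p.s0_base + m.delta_s0)
    if np.any(np.asarray(d) <= 0):
        raise ValueError("degenerate geometry: distance to threshold must be positive")
    tau_eff = max(p.tau + m.delta_ndt, 0.0)
    return d, m.rate_scale * p.mu_r, tau_eff


def later_density(t, p: LATERParams, m: TrialModulation = IDENTITY_MODULATION):
    """Density of RT under the (rate-truncated) LATER model.

    With D the distance to threshold, mu the (scaled) mean rate, sigma the
    rate SD and tau_eff the effective NDT:

        f(t) = [D / (t - tau_eff)^2] * phi((D/(t - tau_eff) - mu) / sigma)
               / (sigma * Phi(mu / sigma))      for t > tau_eff, else 0.
    """
    p.validate()
    d, mu, tau_eff = _later_geometry(p, m)
    t = np.asarray(t, dtype=float)
    dt = t - tau_eff
    out = np.zeros_like(dt)
    ok = dt > 0
    r = d / dt[ok]
    z = (r - mu) / p.sigma_r
    norm = p.sigma_r * stats.norm.cdf(mu / p.sigma_r)
    out[ok] = (d / dt[ok] ** 2) * np.exp(-0.5 * z**2) / (_SQRT_2PI * norm)
    return out if out.ndim else float(out)


def _later_sample(p: LATERParams, m: TrialModulation, n: int, rng) -> np.ndarray:
    d, mu, tau_eff = _later_geometry(p, m)
    a = (0.0 - mu) / p.sigma_r  # truncate rates at zero
    r = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=p.sigma_r, size=n, random_state=rng)
    return tau_eff + d / r


# ---------------------------------------------------------------------------
# DDM: exact Wiener first-passage-time density (Navarro & Fuss style series)


def _wfpt_lower(t, v, a: float, w, err: float = 1e-8):
    """Density of first passage through the LOWER boundary at time t.

    Unit diffusion; boundaries {0, a}; relative start w = z / a; drift v.
    ``t``, ``v`` and ``w`` broadcast elementwise (per-trial modulation moves
    both the drift and the start). Uses the small-time series for small
    normalized time and the large-time series otherwise, with the truncation
    depth chosen per element (Navarro & Fuss 2009).
    """
    t, v, w = np.broadcast_arrays(
        np.asarray(t, dtype=float), np.asarray(v, dtype=float), np.asarray(w, dtype=float)
    )
    out = np.zeros_like(t)
    pos = t > 0
    if not np.any(pos):
        return out
    tt = t[pos] / a**2  # normalized time
    vv = v[pos]
    ww = w[pos]

    with np.errstate(divide="ignore", invalid="ignore"):
        ks = 2.0 + np.sqrt(-2.0 * tt * np.log(2.0 * np.sqrt(2.0 * np.pi * tt) * err))
        ks = np.where(2.0 * np.sqrt(2.0 * np.pi * tt) * err < 1.0, ks, 2.0)
        ks = np.maximum(ks, np.sqrt(tt) + 1.0)
        kl = np.sqrt(-2.0 * np.log(np.pi * tt * err) / (np.pi**2 * tt))
        kl = np.where(np.pi * tt * err < 1.0, kl, 1.0 / (np.pi * np.sqrt(tt)))

    use_small = ks < kl
    f = np.zeros_like(tt)

    if np.any(use_small):
        ts = tt[use_small]
        ws = ww[use_small]
        K = int(np.ceil(np.max(ks[use_small])))
        kk = np.arange(-((K - 1) // 2), ((K - 1) // 2) + 1)
        wk = ws[:, None] + 2.0 * kk[None, :]
        f_s = np.sum(wk * np.exp(-(wk**2) / (2.0 * ts[:, None])), axis=1)
        f[use_small] = f_s / np.sqrt(2.0 * np.pi * ts**3)

    if np.any(~use_small):
        tl = tt[~use_small]
        wl = ww[~use_small]
        K = int(np.ceil(np.max(kl[~use_small])))
        kk = np.arange(1, K + 1)
        f_l = np.sum(
            kk[None, :]
            * np.exp(-(kk[None, :] ** 2) * np.pi**2 * tl[:, None] / 2.0)
            * np.sin(kk[None, :] * np.pi * wl[:, None]),
            axis=1,
        )
        f[~use_small] = f_l * np.pi

    # un-normalize: drift term and boundary scaling
    f = f * np.exp(-vv * a * ww - vv**2 * t[pos] / 2.0) / a**2
    out[pos] = np.maximum(f, 0.0)
    return out


def _ddm_geometry(p: DDMParams, m: TrialModulation):
    z = p.theta / 2.0 + (p.s0_base + m.delta_s0)
    z = np.clip(z, _START_EPS * p.theta, (1.0 - _START_EPS) * p.theta)
    drift = m.rate_scale * p.r
    tau_eff = max(p.tau + m.delta_ndt, 0.0)
    return z, drift, tau_eff


def ddm_fpt_density(
    t,
    p: DDMParams,
    m: TrialModulation = IDENTITY_MODULATION,
    boundary: str = "correct",
):
    """First-passage-time density at the named boundary ('correct' = upper).

    The two sub-densities (correct + error) jointly integrate to 1 over
    t > tau_eff. Diffusion coefficient s is absorbed by rescaling the
    process to unit diffusion.
    """
    p.validate()
    z, drift, tau_eff = _ddm_geometry(p, m)
    a = p.theta / p.s
    v = drift / p.s
    w = z / p.theta  # relative start, invariant to the rescaling
    t = np.asarray(t, dtype=float)
    td = t - tau_eff
    if boundary == "correct":
        out = _wfpt_lower(td, -v, a, 1.0 - w)
    elif boundary == "error":
        out = _wfpt_lower(td, v, a, w)
    else:
        raise ValueError("boundary must be 'correct' or 'error'")
    return out if out.ndim else float(out)


def ddm_upper_probability(p: DDMParams, m: TrialModulation = IDENTITY_MODULATION) -> float:
    """Probability of absorption at the upper (correct) boundary."""
    z, drift, _ = _ddm_geometry(p, m)
    s2 = p.s**2
    if abs(drift) < 1e-12:
        return float(z / p.theta)
    e = np.exp
    return float((1.0 - e(-2.0 * drift * z / s2)) / (1.0 - e(-2.0 * drift * p.theta / s2)))


def _ddm_paths(z, drift, theta: float, s: float, rng, dt: float = 1e-3, t_max: float = 10.0):
    """Euler-Maruyama first-passage sampling, one path per element of z/drift.

    A Brownian-bridge correction accounts for unobserved excursions past a
    boundary between grid points, removing the leading-order discretization
    bias of naive threshold checks, so a moderate step size is accurate.
    Returns (fpt, hit_upper); paths not absorbed by t_max report fpt = t_max.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    drift = np.broadcast_to(np.asarray(drift, dtype=float), z.shape).copy()
    n = z.size
    x = z.copy()
    alive = np.ones(n, dtype=bool)
    fpt = np.full(n, np.nan)
    hit_upper = np.zeros(n, dtype=bool)
    sdt = s * np.sqrt(dt)
    n_steps = int(np.ceil(t_max / dt))
    for step in range(n_steps):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        x_old = x[idx]
        x_new = x_old + drift[idx] * dt + sdt * rng.standard_normal(idx.size)
        t_now = (step + 1) * dt
        crossed_up = x_new >= theta
        crossed_dn = x_new <= 0.0
        inside = ~(crossed_up | crossed_dn)
        if np.any(inside):
            xi, xo = x_new[inside], x_old[inside]
            # bridge probability of an unobserved excursion past either boundary
            p_up = np.exp(-2.0 * (theta - xo) * (theta - xi) / (s**2 * dt))
            p_dn = np.exp(-2.0 * xo * xi / (s**2 * dt))
            u = rng.random(xi.size)
            bridge_up = u < p_up
            bridge_dn = (~bridge_up) & (u < p_up + p_dn)
            sub_idx = np.nonzero(inside)[0]
            crossed_up[sub_idx[bridge_up]] = True
            crossed_dn[sub_idx[bridge_dn]] = True
        done = crossed_up | crossed_dn
        if np.any(done):
            g = idx[done]
            fpt[g] = t_now
            hit_upper[g] = crossed_up[done]
            alive[g] = False
        x[idx[~done]] = x_new[~done]
    # paths that never absorbed within t_max: censor at t_max (caller handles)
    fpt[np.isnan(fpt)] = t_max
    return fpt, hit_upper


def _ddm_sample(
    p: DDMParams, m: TrialModulation, n: int, rng, dt: float = 1e-3, t_max: float = 10.0
):
    z, drift, tau_eff = _ddm_geometry(p, m)
    fpt, hit_upper = _ddm_paths(
        np.full(n, float(z)), float(drift), p.theta, p.s, rng, dt=dt, t_max=t_max
    )
    return tau_eff + fpt, hit_upper


def sample(model: str, params, modulation: TrialModulation, n: int, seed):
    """Draw n (rt, hit_correct_boundary) pairs from the named model.

    For LATER the boundary flag is always True (a single threshold).
    """
    rng = np.random.default_rng(seed)
    if model.upper() == "LATER":
        rts = _later_sample(params, modulation, n, rng)
        return rts, np.ones(n, dtype=bool)
    if model.upper() == "DDM":
        return _ddm_sample(params, modulation, n, rng)
    raise ValueError(f"unknown model {model!r}")


def expected_rt(
    model: str,
    params,
    modulation: TrialModulation = IDENTITY_MODULATION,
    window: tuple[float, float] = (0.2, 1.5),
    n_grid: int = 512,
) -> float:
    """Mean RT under the density restricted and renormalized to ``window``.

    For the DDM the correct-boundary density is used, matching the trials
    that enter the likelihood and the behavioral profile means.
    """
    lo, hi = window
    t = np.linspace(lo, hi, n_grid)
    if model.upper() == "LATER":
        f = later_density(t, params, modulation)
    else:
        f = ddm_fpt_density(t, params, modulation, boundary="correct")
    mass = integrate.trapezoid(f, t)
    if mass <= 0:
        raise ValueError("no probability mass in the requested window")
    return float(integrate.trapezoid(t * f, t) / mass)
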