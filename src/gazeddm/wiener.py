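"""Two-boundary Wiener first-passage density and diffusion simulators.

Conventions: evidence starts at ``beta * alpha`` between absorbing boundaries
0 (healthy option) and ``alpha`` (tasty option), accumulates with constant or
piecewise-constant drift ``v`` and unit diffusion noise.  Response time is the
first-passage (decision) time plus the non-decision time ``ndt``.

The density uses the classic pair of series expansions of the first-passage
distribution in rescaled time ``u = t / alpha**2``: a "small-time" sum over
image charges and a "large-time" Fourier sine series.  Per evaluation the
expansion needing fewer terms for a truncation error below ``SERIES_EPS`` is
selected elementwise (Navarro–Fuss switching rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "DriftSchedule",
    "choice_prob_closed_form",
    "wiener_logpdf",
    "simulate_first_passage",
    "simulate_constant_drift",
]

#: absolute truncation error of the first-passage density series
SERIES_EPS = 1e-7
#: default Euler–Maruyama step (seconds)
DEFAULT_DT = 1e-3


@dataclass
class DriftSchedule:
    """Piecewise-constant drift: per-segment instantaneous drift and duration (s).

    When the schedule is exhausted before absorption the last segment's drift
    persists.  A single-segment schedule is a constant-drift process.
    """

    drifts: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        self.drifts = np.atleast_1d(np.asarray(self.drifts, dtype=float))
        self.durations = np.atleast_1d(np.asarray(self.durations, dtype=float))
        if self.drifts.shape != self.durations.shape:
            raise ValueError("drifts and durations must align")
        if np.any(self.durations <= 0):
            raise ValueError("segment durations must be positive")

    @property
    def average_drift(self) -> float:
        """Duration-weighted mean drift over the scheduled segments."""
        return float(np.average(self.drifts, weights=self.durations))


def choice_prob_closed_form(v, alpha, beta):
    """P(absorption at the upper boundary) for constant drift, unit noise.

    ``(1 - exp(-2 v beta alpha)) / (1 - exp(-2 v alpha))``, with the
    driftless limit ``beta`` taken where ``v`` is (numerically) zero.
    """
    v = np.asarray(v, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    if np.any((beta <= 0) | (beta >= 1)):
        raise ValueError("beta must lie in (0, 1)")
    small = np.abs(v * alpha) < 1e-8
    vs = np.where(small, 1.0, v)  # placeholder to avoid 0/0
    with np.errstate(over="ignore"):
        p = np.expm1(-2.0 * vs * beta * alpha) / np.expm1(-2.0 * vs * alpha)
    out = np.where(small, beta, p)
    return out.item() if out.ndim == 0 else out


@njit(cache=True)
def _loglik_core(rt, upper, v, alpha, beta, ndt, eps0):  # pragma: no cover - jitted
    n = rt.shape[0]
    out = np.empty(n)
    for i in range(n):
        t = rt[i] - ndt[i]
        a = alpha[i]
        if t <= 0.0 or a <= 0.0 or beta[i] <= 0.0 or beta[i] >= 1.0:
            out[i] = -np.inf
            continue
        if upper[i]:
            w = 1.0 - beta[i]
            vv = -v[i]
        else:
            w = beta[i]
            vv = v[i]
        u = t / (a * a)
        eps = eps0 * a * a
        if eps > 0.49:
            eps = 0.49
        # series lengths (Navarro-Fuss switching rule)
        su = np.sqrt(2.0 * np.pi * u)
        if 2.0 * su * eps < 1.0:
            ks = 2.0 + np.sqrt(-2.0 * u * np.log(2.0 * eps * su))
        else:
            ks = 2.0
        lb = np.sqrt(u) + 1.0
        if ks < lb:
            ks = lb
        if np.pi * u * eps < 1.0:
            kl = np.sqrt(-2.0 * np.log(np.pi * u * eps) / (np.pi * np.pi * u))
            lb = 1.0 / (np.pi * np.sqrt(u))
            if kl < lb:
                kl = lb
        else:
            kl = 1.0 / (np.pi * np.sqrt(u))
        f1 = 0.0
        if ks < kl:
            K = int(np.ceil(ks))
            for k in range(-K, K + 1):
                q = w + 2.0 * k
                f1 += q * np.exp(-q * q / (2.0 * u))
            f1 /= np.sqrt(2.0 * np.pi * u * u * u)
        else:
            K = int(np.ceil(kl))
            for k in range(1, K + 1):
                f1 += k * np.exp(-k * k * np.pi * np.pi * u / 2.0) * np.sin(k * np.pi * w)
            f1 *= np.pi
        dens = f1 / (a * a) * np.exp(-vv * a * w - vv * vv * t / 2.0)
        out[i] = np.log(dens) if dens > 0.0 else -np.inf
    return out


def _fpt_density_lower(t, v, alpha, w):
    """Density of absorption at the LOWER boundary at decision time t (>0)."""
    u = t / alpha**2
    # required series lengths (Navarro & Fuss 2009)
    eps = SERIES_EPS * alpha**2  # density error target on the t scale
    eps = np.minimum(eps, 0.49)
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = 2.0 + np.sqrt(np.maximum(-2.0 * u * np.log(2.0 * eps * np.sqrt(2.0 * np.pi * u)), 0.0))
        ks = np.where(2.0 * np.sqrt(2.0 * np.pi * u) * eps < 1.0, ks, 2.0)
        ks = np.maximum(ks, np.sqrt(u) + 1.0)
        kl = np.sqrt(np.maximum(-2.0 * np.log(np.pi * u * eps), 0.0) / (np.pi**2 * u))
        kl = np.where(np.pi * u * eps < 1.0, np.maximum(kl, 1.0 / (np.pi * np.sqrt(u))), 1.0 / (np.pi * np.sqrt(u)))
    use_small = ks < kl

    f1 = np.empty_like(u)
    if np.any(use_small):
        us, wsm = u[use_small], np.broadcast_to(w, u.shape)[use_small]
        K = int(np.ceil(ks[use_small].max()))
        k = np.arange(-K, K + 1)[:, None]
        terms = (wsm + 2 * k) * np.exp(-((wsm + 2 * k) ** 2) / (2 * us))
        f1[use_small] = terms.sum(axis=0) / np.sqrt(2 * np.pi * us**3)
    if np.any(~use_small):
        ul, wl = u[~use_small], np.broadcast_to(w, u.shape)[~use_small]
        K = int(np.ceil(kl[~use_small].max()))
        k = np.arange(1, K + 1)[:, None]
        terms = k * np.exp(-(k**2) * np.pi**2 * ul / 2.0) * np.sin(k * np.pi * wl)
        f1[~use_small] = np.pi * terms.sum(axis=0)

    vb = np.broadcast_to(v, u.shape)
    dens = f1 / alpha**2 * np.exp(-vb * alpha * np.broadcast_to(w, u.shape) - vb**2 * t / 2.0)
    return np.maximum(dens, 0.0)


def wiener_logpdf(rt, upper, v, alpha, beta, ndt):
    """Log density of (boundary, rt) under constant drift and unit noise.

    ``upper`` flags absorption at the upper (tasty) boundary.  RTs at or below
    the non-decision time have density zero (log-density ``-inf``).  All
    arguments broadcast.
    """
    rt = np.asarray(rt, dtype=float)
    upper = np.asarray(upper, dtype=bool)
    v = np.asarray(v, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    ndt = np.asarray(ndt, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    if np.any((beta <= 0) | (beta >= 1)):
        raise ValueError("beta must lie in (0, 1)")

    rt, upper, v, alpha, beta, ndt = np.broadcast_arrays(rt, upper, v, alpha, beta, ndt)
    shape = rt.shape
    out = _loglik_core(
        np.ascontiguousarray(rt, dtype=np.float64).ravel(),
        np.ascontiguousarray(upper, dtype=np.bool_).ravel(),
        np.ascontiguousarray(v, dtype=np.float64).ravel(),
        np.ascontiguousarray(alpha, dtype=np.float64).ravel(),
        np.ascontiguousarray(beta, dtype=np.float64).ravel(),
        np.ascontiguousarray(ndt, dtype=np.float64).ravel(),
        SERIES_EPS,
    ).reshape(shape)
    return out.item() if out.ndim == 0 else out


def simulate_constant_drift(v, alpha, beta, ndt, rng, dt=DEFAULT_DT, t_max=60.0):
    """Euler–Maruyama simulation of many independent constant-drift trials.

    ``v`` is an array of per-trial drifts (``alpha/beta/ndt`` broadcast).
    Returns ``(upper, rt)`` boolean/float arrays.  Paths not absorbed by
    ``t_max`` are assigned the nearer boundary at that time.
    """
    v = np.atleast_1d(np.asarray(v, dtype=float))
    n = v.shape[0]
    alpha_arr = np.broadcast_to(np.asarray(alpha, dtype=float), (n,)).copy()
    beta_arr = np.broadcast_to(np.asarray(beta, dtype=float), (n,)).copy()
    ndt_arr = np.broadcast_to(np.asarray(ndt, dtype=float), (n,)).copy()
    x = beta_arr * alpha_arr
    sqdt = np.sqrt(dt)
    active = np.arange(n)
    upper = np.zeros(n, dtype=bool)
    dtime = np.full(n, t_max)
    n_steps = int(np.ceil(t_max / dt))
    for step in range(1, n_steps + 1):
        x_old = x[active].copy()
        x[active] += v[active] * dt + sqdt * rng.standard_normal(active.size)
        hit_up = x[active] >= alpha_arr[active]
        hit_lo = x[active] <= 0.0
        # Brownian-bridge correction: the path may have touched a boundary
        # inside the step even though both endpoints lie inside; without it
        # the absorption probability carries an O(sqrt(dt)) bias.
        inside = ~(hit_up | hit_lo)
        if np.any(inside):
            xi_o, xi_n = x_old[inside], x[active][inside]
            a_in = alpha_arr[active][inside]
            p_up = np.exp(-2.0 * (a_in - xi_o) * (a_in - xi_n) / dt)
            p_lo = np.exp(-2.0 * xi_o * xi_n / dt)
            u = rng.random(xi_o.size)
            bridge_up = u < p_up
            bridge_lo = (~bridge_up) & (u < p_up + p_lo)
            hit_up[inside] |= bridge_up
            hit_lo[inside] |= bridge_lo
        done = hit_up | hit_lo
        if np.any(done):
            idx = active[done]
            upper[idx] = hit_up[done]
            dtime[idx] = step * dt
            active = active[~done]
            if active.size == 0:
                break
    if active.size:  # censor: nearer boundary at t_max
        upper[active] = x[active] >= alpha_arr[active] / 2.0
    return upper, dtime + ndt_arr


def simulate_piecewise(drifts_flat, durations_flat, offsets, alpha, beta, ndt, rng,
                       dt=DEFAULT_DT, t_max=60.0):
    """Vectorized first-passage simulation of many trials with ragged schedules.

    ``drifts_flat``/``durations_flat`` concatenate all trials' segments;
    ``offsets`` (length n+1) delimits each trial's slice.  The last segment's
    drift persists beyond the scheduled horizon.  Returns ``(upper, rt,
    decision_time)``.
    """
    drifts_flat = np.asarray(drifts_flat, dtype=float)
    durations_flat = np.asarray(durations_flat, dtype=float)
    offsets = np.asarray(offsets, dtype=np.int64)
    n = offsets.size - 1
    alpha_arr = np.broadcast_to(np.asarray(alpha, dtype=float), (n,)).copy()
    beta_arr = np.broadcast_to(np.asarray(beta, dtype=float), (n,)).copy()
    ndt_arr = np.broadcast_to(np.asarray(ndt, dtype=float), (n,)).copy()

    ptr = offsets[:-1].copy()                  # current segment per trial
    last = offsets[1:] - 1
    edge = durations_flat[ptr].copy()          # end time of current segment
    x = beta_arr * alpha_arr
    sqdt = np.sqrt(dt)
    active = np.arange(n)
    upper = np.zeros(n, dtype=bool)
    dtime = np.full(n, t_max)
    n_steps = int(np.ceil(t_max / dt))
    for step in range(1, n_steps + 1):
        t = step * dt
        adv = (t > edge[active]) & (ptr[active] < last[active])
        while np.any(adv):
            idx = active[adv]
            ptr[idx] += 1
            edge[idx] += durations_flat[ptr[idx]]
            adv = (t > edge[active]) & (ptr[active] < last[active])
        v = drifts_flat[ptr[active]]
        x_old = x[active].copy()
        x[active] += v * dt + sqdt * rng.standard_normal(active.size)
        hit_up = x[active] >= alpha_arr[active]
        hit_lo = x[active] <= 0.0
        inside = ~(hit_up | hit_lo)
        if np.any(inside):
            xi_o, xi_n = x_old[inside], x[active][inside]
            a_in = alpha_arr[active][inside]
            p_up = np.exp(-2.0 * (a_in - xi_o) * (a_in - xi_n) / dt)
            p_lo = np.exp(-2.0 * xi_o * xi_n / dt)
            u = rng.random(xi_o.size)
            bridge_up = u < p_up
            bridge_lo = (~bridge_up) & (u < p_up + p_lo)
            hit_up[inside] |= bridge_up
            hit_lo[inside] |= bridge_lo
        done = hit_up | hit_lo
        if np.any(done):
            idx = active[done]
            upper[idx] = hit_up[done]
            dtime[idx] = t
            active = active[~done]
            if active.size == 0:
                break
    if active.size:
        upper[active] = x[active] >= alpha_arr[active] / 2.0
    return upper, dtime + ndt_arr, dtime


def simulate_first_passage(schedule: DriftSchedule, alpha, beta, ndt, dt=DEFAULT_DT,
                           seed=None, rng=None, t_max=60.0):
    """Simulate one first-passage under a piecewise-constant drift schedule.

    Returns a dict with ``upper`` (bool), ``decision_time`` and ``rt``
    (seconds).  The last scheduled drift persists if the schedule runs out
    before absorption; if ``t_max`` is reached the nearer boundary is taken.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not 0 < beta < 1:
        raise ValueError("beta must lie in (0, 1)")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    edges = np.cumsum(schedule.durations)
    x = beta * alpha
    sqdt = np.sqrt(dt)
    n_steps = int(np.ceil(t_max / dt))
    seg = 0
    for step in range(1, n_steps + 1):
        t = step * dt
        while seg < len(edges) - 1 and t > edges[seg]:
            seg += 1
        v = schedule.drifts[min(seg, len(schedule.drifts) - 1)]
        x_old = x
        x += v * dt + sqdt * rng.standard_normal()
        if x >= alpha or x <= 0.0:
            up = x >= alpha
            return {"upper": bool(up), "decision_time": t, "rt": t + ndt}
        # within-step boundary touch (Brownian bridge)
        p_up = np.exp(-2.0 * (alpha - x_old) * (alpha - x) / dt)
        p_lo = np.exp(-2.0 * x_old * x / dt)
        u = rng.random()
        if u < p_up:
            return {"upper": True, "decision_time": t, "rt": t + ndt}
        if u < p_up + p_lo:
            return {"upper": False, "decision_time": t, "rt": t + ndt}
    return {"upper": bool(x >= alpha / 2.0), "decision_time": n_steps * dt,
            "rt": n_steps * dt + ndt}
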