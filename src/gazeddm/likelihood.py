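"""Trial-level likelihood: dwell-weighted drift averaging + Wiener density.

The fitted likelihood follows the piecewise-constant-averaging shortcut: the
gaze-dependent drift schedule of a trial is collapsed to its dwell-weighted
mean drift, and the trial's (choice, RT) pair is evaluated under the
constant-drift two-boundary Wiener density at that mean.  The mean drift
equals ``d * VD`` with the dwell shares of the trial, so the likelihood only
consumes shares, never fixation timing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

import numba

from .models import ModelSpec, ParamSet, value_difference
from .wiener import SERIES_EPS, DriftSchedule, _loglik_core, wiener_logpdf


@numba.njit(cache=True)
def _vd_core(ti, tj, hi, hj, f_it, f_ih, f_jt, f_jh,
             omega, theta, phi_t, phi_h):  # pragma: no cover - jitted
    n = ti.shape[0]
    out = np.empty(n)
    for k in range(n):
        w, th = omega[k], theta[k]
        dt_i = ti[k] - th * tj[k]
        dh_i = hi[k] - th * hj[k]
        dt_j = th * ti[k] - tj[k]
        dh_j = th * hi[k] - hj[k]
        out[k] = (f_it[k] * (w * dt_i + (1 - w) * phi_h[k] * dh_i)
                  + f_ih[k] * (w * phi_t[k] * dt_i + (1 - w) * dh_i)
                  + f_jt[k] * (w * dt_j + (1 - w) * phi_h[k] * dh_j)
                  + f_jh[k] * (w * phi_t[k] * dt_j + (1 - w) * dh_j))
    return out


@numba.njit(cache=True)
def _hier_cond_core(raw, idx, n_sub, rt, upper, ti, tj, hi, hj,
                    f_it, f_ih, f_jt, f_jh, cols, trans, fixed,
                    eps0):  # pragma: no cover - jitted
    """Summed per-participant log-likelihood of one condition, fully fused.

    ``raw`` is the (J, K) raw participant matrix; ``cols[p]`` gives the raw
    column of canonical parameter p (order: alpha, ndt, d, omega, beta,
    theta, phi_t, phi_h) or -1 for a fixed value in ``fixed[p]``;
    ``trans[p]`` is 0 identity, 1 softplus, 2 probit.
    """
    J = raw.shape[0]
    theta_ = np.empty((J, 8))
    for j in range(J):
        for p in range(8):
            if cols[p] < 0:
                theta_[j, p] = fixed[p]
            else:
                x = raw[j, cols[p]]
                if trans[p] == 1:
                    theta_[j, p] = np.log1p(np.exp(-abs(x))) + max(x, 0.0)
                elif trans[p] == 2:
                    theta_[j, p] = 0.5 * (1.0 + math_erf(x / np.sqrt(2.0)))
                else:
                    theta_[j, p] = x
    out = np.zeros(n_sub)
    n = rt.shape[0]
    for i in range(n):
        j = idx[i]
        alpha = theta_[j, 0]
        ndt = theta_[j, 1]
        d = theta_[j, 2]
        w = theta_[j, 3]
        beta = theta_[j, 4]
        th = theta_[j, 5]
        ph_t = theta_[j, 6]
        ph_h = theta_[j, 7]
        dt_i = ti[i] - th * tj[i]
        dh_i = hi[i] - th * hj[i]
        dt_j = th * ti[i] - tj[i]
        dh_j = th * hi[i] - hj[i]
        vd = (f_it[i] * (w * dt_i + (1 - w) * ph_h * dh_i)
              + f_ih[i] * (w * ph_t * dt_i + (1 - w) * dh_i)
              + f_jt[i] * (w * dt_j + (1 - w) * ph_h * dh_j)
              + f_jh[i] * (w * ph_t * dt_j + (1 - w) * dh_j))
        v = d * vd
        t = rt[i] - ndt
        if t <= 0.0 or beta <= 0.0 or beta >= 1.0 or alpha <= 0.0:
            out[j] += -1e300
            continue
        if upper[i]:
            ww = 1.0 - beta
            vv = -v
        else:
            ww = beta
            vv = v
        u = t / (alpha * alpha)
        eps = eps0 * alpha * alpha
        if eps > 0.49:
            eps = 0.49
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
            Kn = int(np.ceil(ks))
            for k in range(-Kn, Kn + 1):
                q = ww + 2.0 * k
                f1 += q * np.exp(-q * q / (2.0 * u))
            f1 /= np.sqrt(2.0 * np.pi * u * u * u)
        else:
            Kn = int(np.ceil(kl))
            for k in range(1, Kn + 1):
                f1 += k * np.exp(-k * k * np.pi * np.pi * u / 2.0) * np.sin(k * np.pi * ww)
            f1 *= np.pi
        dens = f1 / (alpha * alpha) * np.exp(-vv * alpha * ww - vv * vv * t / 2.0)
        out[j] += np.log(dens) if dens > 0.0 else -1e300
    return out


from math import erf as math_erf  # noqa: E402  (needed inside the jit)


def fast_loglik(data: "TrialArrays", p: dict) -> np.ndarray:
    """Per-trial log-likelihood from per-trial constrained parameter arrays.

    Internal fast path for the sampler; ``p`` maps the eight parameter names
    to float64 arrays aligned with ``data``.  Semantically identical to
    :func:`dataset_loglik`.
    """
    vd = _vd_core(*data.values, *data.dwell,
                  p["omega"], p["theta"], p["phi_t"], p["phi_h"])
    return _loglik_core(data.rt, data.choice_tasty, p["d"] * vd,
                        p["alpha"], p["beta"], p["ndt"], SERIES_EPS)

__all__ = [
    "TrialArrays",
    "drift_schedule",
    "trial_drift_average",
    "trial_loglik",
    "dataset_loglik",
]

_AOI_TO_SHARES = {
    "i_taste": (1.0, 0.0, 0.0, 0.0),
    "i_health": (0.0, 1.0, 0.0, 0.0),
    "j_taste": (0.0, 0.0, 1.0, 0.0),
    "j_health": (0.0, 0.0, 0.0, 1.0),
}


@dataclass
class TrialArrays:
    """Columnar view of an oriented trial table, ready for vectorized likelihoods."""

    participant: np.ndarray      # 0-based participant index
    hungry: np.ndarray           # bool, condition indicator
    rt: np.ndarray
    choice_tasty: np.ndarray     # bool, upper-boundary choice
    values: tuple                # (t_i, t_j, h_i, h_j)
    dwell: tuple                 # (f_it, f_ih, f_jt, f_jh)
    participant_ids: np.ndarray  # original labels, index-aligned

    @property
    def n_trials(self) -> int:
        return self.rt.size

    @property
    def n_participants(self) -> int:
        return self.participant_ids.size

    @staticmethod
    def from_frame(trials: pd.DataFrame, hungry_label: str = "hungry") -> "TrialArrays":
        ids, idx = np.unique(trials["participant"].to_numpy()), None
        idx = pd.Categorical(trials["participant"], categories=ids).codes.astype(np.int64)
        get = lambda c: trials[c].to_numpy(dtype=float)
        return TrialArrays(
            participant=idx,
            hungry=trials["condition"].eq(hungry_label).to_numpy(),
            rt=get("rt"),
            choice_tasty=trials["choice_tasty"].to_numpy(dtype=bool),
            values=(get("taste_i"), get("taste_j"), get("health_i"), get("health_j")),
            dwell=(get("f_it"), get("f_ih"), get("f_jt"), get("f_jh")),
            participant_ids=ids,
        )


def drift_schedule(spec: ModelSpec, params: ParamSet, values, aois, durations) -> DriftSchedule:
    """Instantaneous drift per fixation segment of one trial.

    ``aois`` is a sequence of AOI labels (``i_taste`` ...; ``none`` segments
    are dropped), ``durations`` the matching dwell times.  The drift while
    fixating one region is ``d`` times the value difference evaluated with a
    one-hot dwell vector on that region.
    """
    drifts, durs = [], []
    for aoi, dur in zip(aois, durations):
        if aoi not in _AOI_TO_SHARES:
            continue
        vd = value_difference(spec, params, values, _AOI_TO_SHARES[aoi])
        drifts.append(params.d * float(vd))
        durs.append(float(dur))
    if not drifts:
        raise ValueError("trial has no AOI fixations; exclude it upstream")
    return DriftSchedule(np.array(drifts), np.array(durs))


def trial_drift_average(spec: ModelSpec, params: ParamSet, values, aois, durations) -> float:
    """Dwell-weighted mean drift of one trial's fixation stream.

    Identical to ``d * value_difference(...)`` with the trial's dwell shares —
    the averaging collapses segmentwise drifts into the share-weighted VD.
    """
    return drift_schedule(spec, params, values, aois, durations).average_drift


def trial_loglik(spec: ModelSpec, params: ParamSet, rt, choice_tasty, values, dwell) -> float:
    """Log-likelihood of one trial's (choice, RT) at its averaged drift."""
    v = params.d * value_difference(spec, params, values, dwell)
    return float(wiener_logpdf(rt, choice_tasty, v, params.alpha, params.beta,
                               params.ndt, ))


def dataset_loglik(spec: ModelSpec, data: TrialArrays, params: ParamSet,
                   per_trial: bool = False):
    """Vectorized log-likelihood of many trials.

    ``params`` fields are scalars or arrays already aligned to trials (use
    fancy indexing by ``data.participant`` to expand per-participant values).
    Returns the per-trial vector if ``per_trial`` else the sum.
    """
    v = params.d * value_difference(spec, params, data.values, data.dwell)
    ll = wiener_logpdf(data.rt, data.choice_tasty, v, params.alpha, params.beta,
                       params.ndt)
    return ll if per_trial else float(np.sum(ll))
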