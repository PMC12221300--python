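"""Hierarchical Bayesian estimation of the diffusion-model family.

Parameterization follows the condition-difference scheme: each participant j
carries a raw-scale ``baseline`` vector (the sated condition) and a raw-scale
``change`` vector, with ``raw_hungry = raw_baseline + change`` applied before
the softplus / probit transforms.  Both blocks are hierarchical: participant
values are normal around group means with group SDs, and the group means/SDs
carry normal / half-normal hyperpriors.

Sampling is an adaptive Metropolis-within-Gibbs scheme in the spirit of the
Gibbs-sampling toolchains traditionally used for these models: componentwise
random-walk updates of participant parameters (vectorized across
participants, whose likelihoods are independent given the group level),
conjugate Gibbs draws for group means, and random-walk updates on the log of
group SDs.  Proposal scales adapt toward a 0.44 acceptance rate during
burn-in and are frozen afterwards.  Convergence is gated on the
Gelman-Rubin statistic (split-chain Rhat <= 1.05 for every estimated
quantity) and model fit is summarized by the DIC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .likelihood import TrialArrays, _hier_cond_core
from .models import ModelSpec, ParamSet, constrain_params, model_registry
from .models import POSITIVE_PARAMS, UNIT_PARAMS, inv_softplus
from .wiener import SERIES_EPS

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PRESETS",
    "FitResult",
    "build_prior_spec",
    "transform_params",
    "assemble_condition_params",
    "rhat",
    "dic",
    "fit_hierarchical",
    "HierarchicalDDM",
]

RHAT_THRESHOLD = 1.05
_TARGET_ACC = 0.44


# ---------------------------------------------------------------------------
# priors and transforms

@dataclass
class PriorSpec:
    """Normal group-mean and half-normal group-SD hyperpriors per parameter.

    ``baseline[p] = ((mean_loc, mean_scale), sd_scale)`` and likewise for the
    ``change`` block.  A zero scale freezes the block of that parameter at
    the prior location (used to collapse the two-condition model to a pooled
    one).
    """

    baseline: dict = field(default_factory=dict)
    change: dict = field(default_factory=dict)

    def override(self, block: str, param: str, mean=None, sd=None) -> "PriorSpec":
        """Return a copy with one entry replaced; all other rows untouched."""
        new = PriorSpec({k: v for k, v in self.baseline.items()},
                        {k: v for k, v in self.change.items()})
        tbl = getattr(new, block)
        cur_mean, cur_sd = tbl[param]
        tbl[param] = (mean if mean is not None else cur_mean,
                      sd if sd is not None else cur_sd)
        return new


def build_prior_spec(spec: ModelSpec) -> PriorSpec:
    """Default hyperpriors of the study for a given model variant.

    Baseline block: ``alpha ~ N(2,1)/HN(0,3)``, ``ndt ~ N(-1,1)/HN(0,1)``,
    all remaining parameters ``N(0,0.5)/HN(0,0.5)``.  Change block: ``alpha``
    and ``ndt`` ``N(0,1)/HN(0,1)``, all remaining ``N(0,0.25)/HN(0,0.25)``.
    """
    baseline, change = {}, {}
    for p in spec.estimated:
        if p == "alpha":
            baseline[p] = ((2.0, 1.0), 3.0)
            change[p] = ((0.0, 1.0), 1.0)
        elif p == "ndt":
            baseline[p] = ((-1.0, 1.0), 1.0)
            change[p] = ((0.0, 1.0), 1.0)
        else:
            baseline[p] = ((0.0, 0.5), 0.5)
            change[p] = ((0.0, 0.25), 0.25)
    return PriorSpec(baseline, change)


def transform_params(spec: ModelSpec, raw: dict) -> ParamSet:
    """Raw-to-constrained map (softplus for alpha/ndt, probit for beta/omega)."""
    return constrain_params(spec, raw)


def assemble_condition_params(baseline_raw: dict, change_raw: dict, condition: str) -> dict:
    """Raw parameters of one condition: sated = baseline, hungry = baseline + change."""
    if set(baseline_raw) != set(change_raw):
        raise ValueError("baseline and change blocks must cover the same parameters")
    if condition == "sated":
        return dict(baseline_raw)
    if condition == "hungry":
        return {k: baseline_raw[k] + change_raw[k] for k in baseline_raw}
    raise ValueError(f"unknown condition {condition!r}")


# ---------------------------------------------------------------------------
# convergence / fit metrics

def rhat(draws: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``draws`` has shape (chains, n).  Each chain is split in half; the
    statistic compares between- and within-chain variances.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need draws of shape (chains >= 2, n >= 2)")
    m, n = draws.shape
    half = n // 2
    chains = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    w = chains.var(axis=1, ddof=1).mean()
    b = half * chains.mean(axis=1).var(ddof=1)
    if w == 0:
        warnings.warn("zero within-chain variance in rhat", stacklevel=2)
        return np.inf if b > 0 else 1.0
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def dic(deviance: np.ndarray, deviance_at_mean: float) -> dict:
    """Spiegelhalter DIC with both penalty variants.

    ``pD = mean(D) - D(posterior mean)`` and the variance-based alternative
    ``pV = var(D) / 2``; ``DIC = mean(D) + pD``.
    """
    d = np.asarray(deviance, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty deviance trace")
    dbar = float(d.mean())
    p_d = dbar - float(deviance_at_mean)
    p_v = float(d.var(ddof=1) / 2.0) if d.size > 1 else 0.0
    return {"dic": dbar + p_d, "p_d": p_d, "p_v": p_v, "dbar": dbar,
            "dic_pv": dbar + p_v}


# ---------------------------------------------------------------------------
# sampler configuration and result container

@dataclass
class MCMCConfig:
    chains: int = 4
    iterations: int = 4000
    burn_in: int = 2000
    thin: int = 2

    @property
    def n_draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


PRESETS = {
    "test": MCMCConfig(4, 4000, 2000, 2),
    "paper": MCMCConfig(8, 60000, 30000, 12),
}


@dataclass
class FitResult:
    """Posterior draws, convergence diagnostics and fit metrics of one model."""

    model: str
    param_names: tuple
    participant_ids: np.ndarray
    draws: dict                      # name -> array (chains, draws, ...)
    deviance: np.ndarray             # (chains, draws)
    rhat: dict                       # quantity name -> float
    dic: float
    p_d: float
    p_v: float
    dbar: float
    converged: bool
    max_rhat: float
    config: MCMCConfig
    seed: int
    dataset_fingerprint: str = ""

    @property
    def spec(self) -> ModelSpec:
        return model_registry(self.model)

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one quantity with chains flattened (draws, ...)."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def group_posterior(self) -> pd.DataFrame:
        """Posterior summary of group means: transformed per condition, raw change.

        Condition-level rows are on the constrained (interpretable) scale;
        the hunger effect is reported on the raw scale, where 0 means no
        change.
        """
        mu_b = self.stacked("mu_baseline")
        mu_c = self.stacked("mu_change")
        rows = []
        for k, p in enumerate(self.param_names):
            for label, raw_draws in (("sated", mu_b[:, k]),
                                     ("hungry", mu_b[:, k] + mu_c[:, k]),
                                     ("change", mu_c[:, k])):
                x = raw_draws
                if label != "change":
                    if p in POSITIVE_PARAMS:
                        x = np.logaddexp(0.0, x)
                    elif p in UNIT_PARAMS:
                        from scipy.special import ndtr
                        x = ndtr(x)
                lo, hi = _hdi(x, 0.95)
                rows.append({"parameter": p, "condition": label,
                             "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)),
                             "hdi_2.5": lo, "hdi_97.5": hi})
        return pd.DataFrame(rows)

    def participant_raw_means(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Posterior-mean raw baseline and change per participant."""
        b = self.stacked("baseline").mean(axis=0)
        c = self.stacked("change").mean(axis=0)
        cols = list(self.param_names)
        return (pd.DataFrame(b, columns=cols, index=self.participant_ids),
                pd.DataFrame(c, columns=cols, index=self.participant_ids))

    def save(self, path) -> None:
        from pathlib import Path
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "draws.npz", deviance=self.deviance,
                 **{f"draws_{k}": v for k, v in self.draws.items()})
        meta = {
            "model": self.model, "param_names": list(self.param_names),
            "participant_ids": [str(x) for x in self.participant_ids],
            "rhat": {k: float(v) for k, v in self.rhat.items()},
            "dic": self.dic, "p_d": self.p_d, "p_v": self.p_v, "dbar": self.dbar,
            "converged": self.converged, "max_rhat": self.max_rhat,
            "config": asdict(self.config), "seed": self.seed,
            "dataset_fingerprint": self.dataset_fingerprint,
        }
        (path / "fit.json").write_text(json.dumps(meta, indent=1))

    @staticmethod
    def load(path) -> "FitResult":
        from pathlib import Path
        path = Path(path)
        meta = json.loads((path / "fit.json").read_text())
        with np.load(path / "draws.npz") as z:
            deviance = z["deviance"]
            draws = {k[6:]: z[k] for k in z.files if k.startswith("draws_")}
        return FitResult(
            model=meta["model"], param_names=tuple(meta["param_names"]),
            participant_ids=np.array(meta["participant_ids"]),
            draws=draws, deviance=deviance, rhat=meta["rhat"], dic=meta["dic"],
            p_d=meta["p_d"], p_v=meta["p_v"], dbar=meta["dbar"],
            converged=meta["converged"], max_rhat=meta["max_rhat"],
            config=MCMCConfig(**meta["config"]), seed=meta["seed"],
            dataset_fingerprint=meta.get("dataset_fingerprint", ""),
        )


def _hdi(x: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval of a 1-D sample."""
    x = np.sort(np.asarray(x, dtype=float).ravel())
    n = x.size
    k = max(int(np.floor(mass * n)), 1)
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    lo = int(np.argmin(widths))
    return float(x[lo]), float(x[lo + k])


# ---------------------------------------------------------------------------
# the estimator

class HierarchicalDDM:
    """Hierarchical Bayesian gaze-weighted DDM, sklearn-style estimator.

    Parameters
    ----------
    model : str
        One of the eight registered variants (``DDM`` ... ``maaDDM2phi_sp``).
    priors : PriorSpec, optional
        Hyperpriors; defaults to the study's.
    preset : str
        ``"test"`` (4 chains x 4000 iterations, 2000 burn-in, thinning 2) or
        ``"paper"`` (8 x 60000, 30000 burn-in, thinning 12).  Ignored when an
        explicit ``config`` is given.
    random_state : int
        Seed controlling every chain.

    After :meth:`fit` the instance exposes ``result_`` (a :class:`FitResult`)
    plus the convenience attributes ``dic_``, ``rhat_``, ``converged_``.
    """

    def __init__(self, model: str = "maaDDM2phi", priors: PriorSpec | None = None,
                 preset: str = "test", config: MCMCConfig | None = None,
                 random_state: int = 0):
        self.model = model
        self.priors = priors
        self.preset = preset
        self.config = config
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"model": self.model, "priors": self.priors, "preset": self.preset,
                "config": self.config, "random_state": self.random_state}

    def set_params(self, **params) -> "HierarchicalDDM":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- model internals ----------------------------------------------------
    def _cond_loglik(self, raw_matrix: np.ndarray, cond: str) -> np.ndarray:
        """Per-participant summed log-likelihood of one condition's trials."""
        sub, idx, cols, trans, fixed = self._subsets[cond]
        return _hier_cond_core(raw_matrix, idx, self._n_sub, sub.rt,
                               sub.choice_tasty, *sub.values, *sub.dwell,
                               cols, trans, fixed, SERIES_EPS)

    def _run_chain(self, rng: np.random.Generator, cfg: MCMCConfig, priors: PriorSpec):
        J, K = self._n_sub, len(self._param_names)
        names = self._param_names
        pb, pc = priors.baseline, priors.change

        frozen_c = np.array([pc[p][0][1] == 0 and pc[p][1] == 0 for p in names])

        # overdispersed but likelihood-safe initialization
        b = np.empty((J, K))
        c = np.zeros((J, K))
        mu_b = np.empty(K)
        sd_b = np.empty(K)
        mu_c = np.zeros(K)
        sd_c = np.zeros(K)
        for k, p in enumerate(names):
            (m0, s0), t0 = pb[p]
            mu_b[k] = m0 + rng.normal(0, 0.3 * s0)
            sd_b[k] = abs(rng.normal(0, 0.3 * t0)) + 0.1
            b[:, k] = mu_b[k] + rng.normal(0, 0.15, size=J)
            if not frozen_c[k]:
                (mc0, sc0), tc0 = pc[p]
                mu_c[k] = mc0 + rng.normal(0, 0.3 * sc0)
                sd_c[k] = abs(rng.normal(0, 0.3 * tc0)) + 0.05
                c[:, k] = mu_c[k] + rng.normal(0, 0.05, size=J)
        if "ndt" in names:
            k = names.index("ndt")
            cap = inv_softplus(np.maximum(0.6 * self._min_rt, 1e-3))
            b[:, k] = np.minimum(b[:, k], cap)
            c[:, k] = np.minimum(c[:, k], 0.0)

        ll_s = self._cond_loglik(b, "sated")
        ll_h = self._cond_loglik(b + c, "hungry")

        scale_b = np.full((J, K), 0.15)
        scale_c = np.full((J, K), 0.1)
        scale_sd = np.full((2, K), 0.2)
        scale_asis = np.full((2, K), 0.1)

        # joint adaptive-Metropolis state over z_j = (b_j, active c_j):
        # componentwise walks mix slowly along correlated directions (d with
        # omega/alpha), so a covariance-informed joint proposal is added.
        act = np.flatnonzero(~frozen_c)
        D = K + act.size
        am_mean = np.zeros((J, D))
        am_cov = np.zeros((J, D, D))
        am_n = 0
        am_L = np.tile(np.eye(D) * 0.05, (J, 1, 1))
        am_lam = np.ones(J)
        start_joint = min(300, cfg.burn_in // 2)

        def _zvec():
            return np.concatenate([b, c[:, act]], axis=1) if act.size else b.copy()

        n_keep = cfg.n_draws_per_chain
        out = {
            "mu_baseline": np.empty((n_keep, K)), "sd_baseline": np.empty((n_keep, K)),
            "mu_change": np.empty((n_keep, K)), "sd_change": np.empty((n_keep, K)),
            "baseline": np.empty((n_keep, J, K)), "change": np.empty((n_keep, J, K)),
        }
        deviance = np.empty(n_keep)
        kept = 0

        for it in range(cfg.iterations):
            adapting = it < cfg.burn_in
            gamma = (it + 1) ** -0.6 if adapting else 0.0

            # componentwise and interweaving sweeps alternate across
            # iterations: each costs ~3K likelihood evaluations, and running
            # them on alternate iterations nearly halves the cost per
            # iteration at a small price in per-iteration mixing
            comp_sweep = it % 2 == 0 or it < 200
            asis_sweep = it % 2 == 1 or it < 200
            for k in range(K if comp_sweep else 0):
                # participant baseline component k (vectorized across j)
                prop = b.copy()
                step = scale_b[:, k] * rng.standard_normal(J)
                prop[:, k] = b[:, k] + step
                ll_s_p = self._cond_loglik(prop, "sated")
                ll_h_p = self._cond_loglik(prop + c, "hungry")
                d_prior = (-(prop[:, k] - mu_b[k]) ** 2 + (b[:, k] - mu_b[k]) ** 2) / (2 * sd_b[k] ** 2)
                log_r = ll_s_p - ll_s + ll_h_p - ll_h + d_prior
                acc = np.log(rng.random(J)) < log_r
                b[acc, k] = prop[acc, k]
                ll_s = np.where(acc, ll_s_p, ll_s)
                ll_h = np.where(acc, ll_h_p, ll_h)
                if adapting:
                    scale_b[:, k] *= np.exp(gamma * (acc.astype(float) - _TARGET_ACC))

                if frozen_c[k]:
                    continue
                # participant change component k (hungry likelihood only)
                propc = c.copy()
                propc[:, k] = c[:, k] + scale_c[:, k] * rng.standard_normal(J)
                ll_h_p = self._cond_loglik(b + propc, "hungry")
                d_prior = (-(propc[:, k] - mu_c[k]) ** 2 + (c[:, k] - mu_c[k]) ** 2) / (2 * sd_c[k] ** 2)
                log_r = ll_h_p - ll_h + d_prior
                acc = np.log(rng.random(J)) < log_r
                c[acc, k] = propc[acc, k]
                ll_h = np.where(acc, ll_h_p, ll_h)
                if adapting:
                    scale_c[:, k] *= np.exp(gamma * (acc.astype(float) - _TARGET_ACC))

            # joint participant update along the adapted covariance
            if it >= start_joint:
                if adapting and (it % 50 == 0 or it == cfg.burn_in - 1) and am_n > 2 * D:
                    cov = am_cov / max(am_n - 1, 1)
                    cov = cov + 1e-6 * np.eye(D)
                    try:
                        am_L = np.linalg.cholesky(2.38**2 / D * cov)
                    except np.linalg.LinAlgError:
                        pass
                for _rep in range(2):
                    xi = rng.standard_normal((J, D))
                    step = am_lam[:, None] * np.einsum("jab,jb->ja", am_L, xi)
                    prop_b = b + step[:, :K]
                    prop_c = c.copy()
                    if act.size:
                        prop_c[:, act] = c[:, act] + step[:, K:]
                    ll_s_p = self._cond_loglik(prop_b, "sated")
                    ll_h_p = self._cond_loglik(prop_b + prop_c, "hungry")
                    d_prior = (
                        ((b - mu_b) ** 2 - (prop_b - mu_b) ** 2) / (2 * sd_b**2)).sum(axis=1)
                    if act.size:
                        d_prior += (((c[:, act] - mu_c[act]) ** 2
                                     - (prop_c[:, act] - mu_c[act]) ** 2)
                                    / (2 * sd_c[act] ** 2)).sum(axis=1)
                    log_r = ll_s_p - ll_s + ll_h_p - ll_h + d_prior
                    acc = np.log(rng.random(J)) < log_r
                    b[acc] = prop_b[acc]
                    c[acc] = prop_c[acc]
                    ll_s = np.where(acc, ll_s_p, ll_s)
                    ll_h = np.where(acc, ll_h_p, ll_h)
                    if adapting:
                        am_lam *= np.exp(gamma * (acc.astype(float) - 0.234))

            if adapting:
                z = _zvec()
                am_n += 1
                delta = z - am_mean
                am_mean += delta / am_n
                am_cov += np.einsum("ja,jb->jab", delta, z - am_mean)

            # group means: conjugate normal draws
            for k, p in enumerate(names):
                (m0, s0), _ = pb[p]
                var = 1.0 / (1.0 / s0**2 + J / sd_b[k] ** 2)
                mean = var * (m0 / s0**2 + b[:, k].sum() / sd_b[k] ** 2)
                mu_b[k] = mean + np.sqrt(var) * rng.standard_normal()
                if frozen_c[k]:
                    continue
                (mc0, sc0), _ = pc[p]
                var = 1.0 / (1.0 / sc0**2 + J / sd_c[k] ** 2)
                mean = var * (mc0 / sc0**2 + c[:, k].sum() / sd_c[k] ** 2)
                mu_c[k] = mean + np.sqrt(var) * rng.standard_normal()

            # interweaving (ASIS): holding the standardized participant values
            # eta_j = (x_j - mu)/sd fixed, move (mu, log sd) jointly.  The
            # centered updates above leave the group scale stuck in the
            # hierarchical funnel when participants are few; the non-centered
            # move restores mixing there.
            for k in range(K if asis_sweep else 0):
                # baseline block
                eta = (b[:, k] - mu_b[k]) / sd_b[k]
                s = scale_asis[0, k]
                mu_p = mu_b[k] + s * rng.standard_normal()
                sd_p = sd_b[k] * np.exp(0.5 * s * rng.standard_normal())
                b_p = b.copy()
                b_p[:, k] = mu_p + sd_p * eta
                ll_s_p = self._cond_loglik(b_p, "sated")
                ll_h_p = self._cond_loglik(b_p + c, "hungry")
                (m0, s0), tau = pb[names[k]]
                log_r = (ll_s_p.sum() + ll_h_p.sum() - ll_s.sum() - ll_h.sum()
                         + (-(mu_p - m0) ** 2 + (mu_b[k] - m0) ** 2) / (2 * s0**2)
                         + (-sd_p**2 + sd_b[k] ** 2) / (2 * tau**2)
                         + np.log(sd_p) - np.log(sd_b[k]))
                if np.log(rng.random()) < log_r:
                    b, mu_b[k], sd_b[k] = b_p, mu_p, sd_p
                    ll_s, ll_h = ll_s_p, ll_h_p
                    acc_asis = 1.0
                else:
                    acc_asis = 0.0
                if adapting:
                    scale_asis[0, k] *= np.exp(gamma * (acc_asis - 0.234))

                if frozen_c[k]:
                    continue
                # change block (hungry likelihood only)
                eta = (c[:, k] - mu_c[k]) / sd_c[k]
                s = scale_asis[1, k]
                mu_p = mu_c[k] + s * rng.standard_normal()
                sd_p = sd_c[k] * np.exp(0.5 * s * rng.standard_normal())
                c_p = c.copy()
                c_p[:, k] = mu_p + sd_p * eta
                ll_h_p = self._cond_loglik(b + c_p, "hungry")
                (mc0, sc0), tauc = pc[names[k]]
                log_r = (ll_h_p.sum() - ll_h.sum()
                         + (-(mu_p - mc0) ** 2 + (mu_c[k] - mc0) ** 2) / (2 * sc0**2)
                         + (-sd_p**2 + sd_c[k] ** 2) / (2 * tauc**2)
                         + np.log(sd_p) - np.log(sd_c[k]))
                if np.log(rng.random()) < log_r:
                    c, mu_c[k], sd_c[k] = c_p, mu_p, sd_p
                    ll_h = ll_h_p
                    acc_asis = 1.0
                else:
                    acc_asis = 0.0
                if adapting:
                    scale_asis[1, k] *= np.exp(gamma * (acc_asis - 0.234))

            # group SDs: random walk on log scale, half-normal prior
            for block, (sd_vec, mu_vec, x, tbl, frozen) in enumerate((
                    (sd_b, mu_b, b, pb, np.zeros(K, bool)),
                    (sd_c, mu_c, c, pc, frozen_c))):
                for k, p in enumerate(names):
                    if frozen[k]:
                        continue
                    tau = tbl[p][1]
                    resid2 = np.sum((x[:, k] - mu_vec[k]) ** 2)

                    def _logpost(s):
                        return (-J * np.log(s) - resid2 / (2 * s**2)
                                - s**2 / (2 * tau**2) + np.log(s))  # + Jacobian

                    for _rep in range(3):  # cheap; repeated for mixing
                        cur = sd_vec[k]
                        prop_sd = cur * np.exp(scale_sd[block, k] * rng.standard_normal())
                        ok = np.log(rng.random()) < _logpost(prop_sd) - _logpost(cur)
                        if ok:
                            sd_vec[k] = prop_sd
                        if adapting:
                            scale_sd[block, k] *= np.exp(gamma * (float(ok) - 0.234))

            if not adapting and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_keep:
                out["mu_baseline"][kept] = mu_b
                out["sd_baseline"][kept] = sd_b
                out["mu_change"][kept] = mu_c
                out["sd_change"][kept] = sd_c
                out["baseline"][kept] = b
                out["change"][kept] = c
                deviance[kept] = -2.0 * (ll_s.sum() + ll_h.sum())
                kept += 1

        return out, deviance

    def fit(self, trials: pd.DataFrame | TrialArrays) -> "HierarchicalDDM":
        """Sample the joint posterior given an oriented, preprocessed trial table."""
        data = trials if isinstance(trials, TrialArrays) else TrialArrays.from_frame(trials)
        self._spec = model_registry(self.model)
        self._param_names = list(self._spec.estimated)
        cfg = self.config or PRESETS[self.preset]
        priors = self.priors or build_prior_spec(self._spec)

        self._n_sub = data.n_participants
        sated = ~data.hungry
        self._subsets = {}
        # canonical parameter layout for the fused likelihood kernel
        canonical = ("alpha", "ndt", "d", "omega", "beta", "theta", "phi_t", "phi_h")
        fixed_vals = {"beta": 0.5, "theta": 1.0, "phi_t": 1.0, "phi_h": 1.0}
        fixed_vals.update(self._spec.fixed)
        cols = np.full(8, -1, dtype=np.int64)
        fixed = np.zeros(8)
        trans = np.array([1, 1, 0, 2, 2, 0, 0, 0], dtype=np.int64)
        for p_i, name in enumerate(canonical):
            if name in self._param_names:
                cols[p_i] = self._param_names.index(name)
            elif name in ("phi_t", "phi_h") and "phi" in self._param_names:
                cols[p_i] = self._param_names.index("phi")
            else:
                fixed[p_i] = fixed_vals.get(name, 0.0)
        for cond, mask in (("sated", sated), ("hungry", data.hungry)):
            sub = TrialArrays(
                participant=np.ascontiguousarray(data.participant[mask], dtype=np.int64),
                hungry=data.hungry[mask],
                rt=np.ascontiguousarray(data.rt[mask]),
                choice_tasty=np.ascontiguousarray(data.choice_tasty[mask]),
                values=tuple(np.ascontiguousarray(v[mask]) for v in data.values),
                dwell=tuple(np.ascontiguousarray(f[mask]) for f in data.dwell),
                participant_ids=data.participant_ids)
            self._subsets[cond] = (sub, sub.participant, cols, trans, fixed)
        self._min_rt = np.array([
            data.rt[data.participant == j].min() if np.any(data.participant == j) else 1.0
            for j in range(self._n_sub)])

        ss = np.random.SeedSequence(self.random_state)
        chain_draws, chain_dev = [], []
        for child in ss.spawn(cfg.chains):
            d, dev = self._run_chain(np.random.default_rng(child), cfg, priors)
            chain_draws.append(d)
            chain_dev.append(dev)
        draws = {k: np.stack([d[k] for d in chain_draws]) for k in chain_draws[0]}
        deviance = np.stack(chain_dev)

        # convergence for every estimated quantity
        rhats: dict[str, float] = {}
        for k, p in enumerate(self._param_names):
            rhats[f"mu_baseline[{p}]"] = rhat(draws["mu_baseline"][:, :, k])
            rhats[f"sd_baseline[{p}]"] = rhat(draws["sd_baseline"][:, :, k])
            if draws["change"][..., k].std() > 0:
                rhats[f"mu_change[{p}]"] = rhat(draws["mu_change"][:, :, k])
                rhats[f"sd_change[{p}]"] = rhat(draws["sd_change"][:, :, k])
            for j in range(self._n_sub):
                rhats[f"baseline[{j},{p}]"] = rhat(draws["baseline"][:, :, j, k])
                if draws["change"][:, :, j, k].std() > 0:
                    rhats[f"change[{j},{p}]"] = rhat(draws["change"][:, :, j, k])
        max_rhat = float(np.nanmax(list(rhats.values())))
        converged = bool(max_rhat <= RHAT_THRESHOLD)
        if not converged:
            warnings.warn(
                f"max Rhat {max_rhat:.3f} exceeds {RHAT_THRESHOLD}; treat estimates with caution",
                stacklevel=2)

        # DIC: deviance at the posterior mean of raw participant parameters
        b_mean = draws["baseline"].reshape(-1, self._n_sub, len(self._param_names)).mean(axis=0)
        c_mean = draws["change"].reshape(-1, self._n_sub, len(self._param_names)).mean(axis=0)
        ll_hat = (self._cond_loglik(b_mean, "sated").sum()
                  + self._cond_loglik(b_mean + c_mean, "hungry").sum())
        metrics = dic(deviance, -2.0 * ll_hat)

        self.result_ = FitResult(
            model=self.model, param_names=tuple(self._param_names),
            participant_ids=data.participant_ids, draws=draws, deviance=deviance,
            rhat=rhats, dic=metrics["dic"], p_d=metrics["p_d"], p_v=metrics["p_v"],
            dbar=metrics["dbar"], converged=converged, max_rhat=max_rhat,
            config=cfg, seed=self.random_state,
            dataset_fingerprint=f"n={data.n_trials},J={data.n_participants}",
        )
        self.dic_ = self.result_.dic
        self.rhat_ = rhats
        self.converged_ = converged
        return self


def fit_hierarchical(spec: ModelSpec | str, trials, mcmc_config: MCMCConfig | None = None,
                     seed: int = 0, priors: PriorSpec | None = None) -> FitResult:
    """Functional wrapper over :class:`HierarchicalDDM`."""
    name = spec if isinstance(spec, str) else spec.name
    est = HierarchicalDDM(model=name, priors=priors, config=mcmc_config,
                          random_state=seed)
    return est.fit(trials).result_
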