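"""Bayesian within-subject multilevel mediation: hunger -> attention -> choice.

Two-equation model on conflict trials, subject j, trial t, with X = 1 for
the hungry condition, mediator M = proportion of dwell time on the tasty
option (person-mean-centered), and Y = 1 for a tasty choice:

    M_tj = (a0 + a0_j) + (a + a_j) X_tj + eps,          eps ~ N(0, sigma_M)
    Y_tj ~ Bernoulli( logit^-1( (b0 + b0_j) + (b + b_j) M_tj + (c' + c'_j) X_tj ) )

The subject slopes (a_j, b_j) are bivariate normal with free correlation;
their covariance enters the population indirect effect

    indirect = a * b + cov(a_j, b_j),        total c = c' + indirect.

Intercepts and the direct-path deviations c'_j are independent normals.
Sampling is adaptive random-walk Metropolis over global parameters plus
vectorized subject-effect updates; convergence is gated on split-chain
Rhat <= 1.05 for the reported paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import rhat

__all__ = ["MediationConfig", "MediationResult", "MultilevelMediation",
           "fit_mediation", "simulate_mediation_data"]


def simulate_mediation_data(n_subjects: int = 50, n_trials: int = 100,
                            a: float = 0.05, b: float = 4.0, c_prime: float = 0.0,
                            a0: float = 0.6, b0: float = 0.3,
                            tau_a: float = 0.02, tau_b: float = 0.5,
                            sigma_m: float = 0.1, seed: int = 0) -> pd.DataFrame:
    """Synthetic conflict-trial table with known mediation structure.

    The mediator (dwell proportion on the tasty option) responds to hunger
    with slope ``a``; the binary choice responds to the person-centered
    mediator with logit slope ``b`` and to hunger directly with ``c_prime``.
    ``n_trials`` is per condition.
    """
    rng = np.random.default_rng(seed)
    rows = []
    a_j = rng.normal(0.0, tau_a, n_subjects)
    b_j = rng.normal(0.0, tau_b, n_subjects)
    for j in range(n_subjects):
        m_all = {}
        for cond, x in (("sated", 0.0), ("hungry", 1.0)):
            m_all[cond] = np.clip(
                a0 + (a + a_j[j]) * x + rng.normal(0, sigma_m, n_trials), 0, 1)
        grand = np.concatenate(list(m_all.values())).mean()
        for cond, x in (("sated", 0.0), ("hungry", 1.0)):
            m = m_all[cond]
            eta = b0 + (b + b_j[j]) * (m - grand) + c_prime * x
            y = rng.random(n_trials) < 1.0 / (1.0 + np.exp(-eta))
            rows.append(pd.DataFrame({
                "participant": j, "condition": cond,
                "f_tasty": m, "f_healthy": 1.0 - m, "choice_tasty": y}))
    return pd.concat(rows, ignore_index=True)

_PATHS = ("a", "b", "c_prime", "c", "indirect")


@dataclass
class MediationConfig:
    chains: int = 3
    iterations: int = 6000
    burn_in: int = 3000
    thin: int = 3
    center: str = "person"        # "person" (within-subject) or "none"
    mediator: str = "proportion"  # "proportion" f_tasty or "difference" f_tasty - f_healthy


@dataclass
class MediationResult:
    paths: pd.DataFrame           # mean, se, ci_2.5, ci_97.5 per path
    rhat: dict
    converged: bool
    n_participants: int
    n_trials: int
    excluded_participants: list

    def path(self, name: str) -> dict:
        row = self.paths.set_index("path").loc[name]
        return row.to_dict()


def _logistic_ll(eta, y):
    # Bernoulli-logit log-likelihood, stable for large |eta|
    return np.where(y, -np.logaddexp(0.0, -eta), -np.logaddexp(0.0, eta))


class MultilevelMediation:
    """sklearn-style estimator for the within-subject mediation model.

    ``fit`` expects a conflict-trial table with columns ``participant``,
    ``condition`` ({sated, hungry}), ``f_tasty`` (and ``f_healthy`` when the
    difference-score mediator is configured) and ``choice_tasty`` (bool).
    """

    def __init__(self, config: MediationConfig | None = None, random_state: int = 0):
        self.config = config
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config, "random_state": self.random_state}

    def set_params(self, **params) -> "MultilevelMediation":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def _run_chain(self, rng, X, M, Y, sub, J, n_iter, burn, thin):
        n = X.size
        # globals: a0, a, b0, b, cp, log_sigma, log_tau (a0,a,b0,b,cp), atanh_rho
        g = {"a0": M.mean(), "a": 0.0, "b0": 0.0, "b": 0.0, "cp": 0.0}
        g = {k: v + rng.normal(0, 0.1) for k, v in g.items()}
        log_sigma = np.log(M.std() + 1e-3) + rng.normal(0, 0.1)
        log_tau = {k: np.log(0.1) + rng.normal(0, 0.2)
                   for k in ("a0", "a", "b0", "b", "cp")}
        zrho = rng.normal(0, 0.3)
        U = np.zeros((J, 5))  # columns: a0_j, a_j, b0_j, b_j, cp_j

        scales_g = {k: 0.05 for k in g}
        scales_aux = {"log_sigma": 0.05, "zrho": 0.2, **{f"t_{k}": 0.2 for k in log_tau}}
        scales_u = np.full(5, 0.1)

        def med_ll_trials(a0, a, u0, u1):
            mu = (a0 + u0[sub]) + (a + u1[sub]) * X
            s = np.exp(log_sigma)
            return -0.5 * ((M - mu) / s) ** 2 - np.log(s)

        def out_ll_trials(b0, b, cp, u2, u3, u4):
            eta = (b0 + u2[sub]) + (b + u3[sub]) * M + (cp + u4[sub]) * X
            return _logistic_ll(eta, Y)

        def by_sub(x):
            return np.bincount(sub, weights=x, minlength=J)

        ll_m = by_sub(med_ll_trials(g["a0"], g["a"], U[:, 0], U[:, 1]))
        ll_y = by_sub(out_ll_trials(g["b0"], g["b"], g["cp"], U[:, 2], U[:, 3], U[:, 4]))

        def prior_u(U):
            """Log prior of subject effects given current scales/correlation."""
            ta0, ta, tb0, tb, tcp = (np.exp(log_tau[k]) for k in ("a0", "a", "b0", "b", "cp"))
            rho = np.tanh(zrho)
            lp = (-0.5 * (U[:, 0] / ta0) ** 2 - np.log(ta0)
                  - 0.5 * (U[:, 2] / tb0) ** 2 - np.log(tb0)
                  - 0.5 * (U[:, 4] / tcp) ** 2 - np.log(tcp))
            # bivariate normal for (a_j, b_j)
            z1, z2 = U[:, 1] / ta, U[:, 3] / tb
            q = (z1**2 - 2 * rho * z1 * z2 + z2**2) / (1 - rho**2)
            lp += -0.5 * q - np.log(ta) - np.log(tb) - 0.5 * np.log(1 - rho**2)
            return lp

        n_keep = (n_iter - burn) // thin
        out = np.empty((n_keep, len(_PATHS)))
        kept = 0
        for it in range(n_iter):
            adapting = it < burn
            gamma = (it + 1) ** -0.6 if adapting else 0.0

            # subject effects, componentwise, vectorized across subjects
            for col in range(5):
                prop = U.copy()
                prop[:, col] = U[:, col] + scales_u[col] * rng.standard_normal(J)
                if col < 2:
                    ll_new = by_sub(med_ll_trials(g["a0"], g["a"], prop[:, 0], prop[:, 1]))
                    ll_old = ll_m
                else:
                    ll_new = by_sub(out_ll_trials(g["b0"], g["b"], g["cp"],
                                                  prop[:, 2], prop[:, 3], prop[:, 4]))
                    ll_old = ll_y
                log_r = ll_new - ll_old + prior_u(prop) - prior_u(U)
                acc = np.log(rng.random(J)) < log_r
                U[acc, col] = prop[acc, col]
                if col < 2:
                    ll_m = np.where(acc, ll_new, ll_m)
                else:
                    ll_y = np.where(acc, ll_new, ll_y)
                if adapting:
                    scales_u[col] *= np.exp(gamma * (acc.mean() - 0.44))

            # global fixed effects
            for k in g:
                prop = dict(g)
                prop[k] = g[k] + scales_g[k] * rng.standard_normal()
                if k in ("a0", "a"):
                    ll_new = by_sub(med_ll_trials(prop["a0"], prop["a"], U[:, 0], U[:, 1]))
                    ll_old_sum, ll_new_sum = ll_m.sum(), ll_new.sum()
                else:
                    ll_new = by_sub(out_ll_trials(prop["b0"], prop["b"], prop["cp"],
                                                  U[:, 2], U[:, 3], U[:, 4]))
                    ll_old_sum, ll_new_sum = ll_y.sum(), ll_new.sum()
                log_r = ll_new_sum - ll_old_sum + (g[k] ** 2 - prop[k] ** 2) / (2 * 10.0**2)
                ok = np.log(rng.random()) < log_r
                if ok:
                    g[k] = prop[k]
                    if k in ("a0", "a"):
                        ll_m = ll_new
                    else:
                        ll_y = ll_new
                if adapting:
                    scales_g[k] *= np.exp(gamma * (float(ok) - 0.44))

            # residual SD of the mediator equation (half-normal prior)
            prop_ls = log_sigma + scales_aux["log_sigma"] * rng.standard_normal()
            old_ls = log_sigma
            log_sigma = prop_ls
            ll_new = by_sub(med_ll_trials(g["a0"], g["a"], U[:, 0], U[:, 1]))
            log_sigma = old_ls
            log_r = (ll_new.sum() - ll_m.sum()
                     + (-np.exp(2 * prop_ls) + np.exp(2 * old_ls)) / 2.0
                     + (prop_ls - old_ls))
            if np.log(rng.random()) < log_r:
                log_sigma = prop_ls
                ll_m = ll_new
                ok = 1.0
            else:
                ok = 0.0
            if adapting:
                scales_aux["log_sigma"] *= np.exp(gamma * (ok - 0.44))

            # random-effect scales and slope correlation (prior-level only)
            lp_old = prior_u(U).sum()
            for k in list(log_tau) + ["zrho"]:
                key = f"t_{k}" if k != "zrho" else "zrho"
                if k == "zrho":
                    old, zrho_prop = zrho, zrho + scales_aux[key] * rng.standard_normal()
                    zrho = zrho_prop
                    lp_new = prior_u(U).sum()
                    zrho = old
                    # uniform prior on rho -> Jacobian of tanh
                    jac = (np.log1p(-np.tanh(zrho_prop) ** 2)
                           - np.log1p(-np.tanh(old) ** 2))
                    log_r = lp_new - lp_old + jac
                else:
                    old = log_tau[k]
                    prop_t = old + scales_aux[key] * rng.standard_normal()
                    log_tau[k] = prop_t
                    lp_new = prior_u(U).sum()
                    log_tau[k] = old
                    # half-normal(1) prior on tau, log-scale Jacobian
                    log_r = (lp_new - lp_old
                             + (-np.exp(2 * prop_t) + np.exp(2 * old)) / 2.0
                             + (prop_t - old))
                ok = np.log(rng.random()) < log_r
                if ok:
                    if k == "zrho":
                        zrho = zrho_prop
                    else:
                        log_tau[k] = prop_t
                    lp_old = lp_new
                if adapting:
                    scales_aux[key] *= np.exp(gamma * (float(ok) - 0.44))

            if not adapting and (it - burn) % thin == 0 and kept < n_keep:
                ta, tb = np.exp(log_tau["a"]), np.exp(log_tau["b"])
                indirect = g["a"] * g["b"] + np.tanh(zrho) * ta * tb
                out[kept] = (g["a"], g["b"], g["cp"], g["cp"] + indirect, indirect)
                kept += 1
        return out

    def fit(self, trials: pd.DataFrame) -> "MultilevelMediation":
        cfg = self.config or MediationConfig()
        df = trials.copy()

        # participants need both conditions for a within-subject contrast
        both = df.groupby("participant")["condition"].nunique()
        excluded = [p for p, k in both.items() if k < 2]
        if excluded:
            warnings.warn(f"excluding {len(excluded)} single-condition participants",
                          stacklevel=2)
            df = df[~df["participant"].isin(excluded)]
        if df.empty:
            raise ValueError("no participants with both conditions")

        if cfg.mediator == "proportion":
            m = df["f_tasty"].to_numpy(dtype=float)
        elif cfg.mediator == "difference":
            m = (df["f_tasty"] - df["f_healthy"]).to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown mediator {cfg.mediator!r}")
        ids = np.unique(df["participant"].to_numpy())
        sub = pd.Categorical(df["participant"], categories=ids).codes.astype(np.int64)
        if cfg.center == "person":
            m = m - np.bincount(sub, weights=m) [sub] / np.bincount(sub)[sub]
        X = df["condition"].eq("hungry").to_numpy(dtype=float)
        Y = df["choice_tasty"].to_numpy(dtype=bool)

        ss = np.random.SeedSequence(self.random_state)
        chains = [self._run_chain(np.random.default_rng(child), X, m, Y, sub,
                                  ids.size, cfg.iterations, cfg.burn_in, cfg.thin)
                  for child in ss.spawn(cfg.chains)]
        draws = np.stack(chains)  # (chains, keep, paths)

        rhats = {p: rhat(draws[:, :, k]) for k, p in enumerate(_PATHS)}
        max_rhat = max(rhats.values())
        converged = max_rhat <= 1.05
        if not converged:
            warnings.warn(f"mediation max Rhat {max_rhat:.3f} exceeds 1.05", stacklevel=2)

        rows = []
        flat = draws.reshape(-1, len(_PATHS))
        for k, p in enumerate(_PATHS):
            x = flat[:, k]
            lo, hi = np.quantile(x, [0.025, 0.975])
            rows.append({"path": p, "mean": float(x.mean()),
                         "se": float(x.std(ddof=1)),
                         "ci_2.5": float(lo), "ci_97.5": float(hi)})
        self.result_ = MediationResult(
            paths=pd.DataFrame(rows), rhat=rhats, converged=converged,
            n_participants=int(ids.size), n_trials=int(X.size),
            excluded_participants=excluded)
        self.paths_ = self.result_.paths
        self.converged_ = converged
        return self


def plot_path_diagram(result: MediationResult, path=None):
    """Triangle path diagram with posterior means and 95% credible intervals."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    nodes = {"X\n(hungry)": (0.1, 0.2), "M\n(dwell tasty)": (0.5, 0.8),
             "Y\n(tasty choice)": (0.9, 0.2)}
    for label, (x, y) in nodes.items():
        ax.annotate(label, (x, y), ha="center", va="center",
                    bbox=dict(boxstyle="round", fc="lightyellow"))
    p = result.paths.set_index("path")

    def _lab(name):
        row = p.loc[name]
        return f"{row['mean']:.2f} [{row['ci_2.5']:.2f}, {row['ci_97.5']:.2f}]"

    arrows = [((0.16, 0.3), (0.42, 0.72), "a = " + _lab("a"), (0.2, 0.58)),
              ((0.58, 0.72), (0.84, 0.3), "b = " + _lab("b"), (0.82, 0.58)),
              ((0.2, 0.2), (0.8, 0.2), "c' = " + _lab("c_prime"), (0.5, 0.12))]
    for start, end, text, pos in arrows:
        ax.annotate("", end, start, arrowprops=dict(arrowstyle="->"))
        ax.annotate(text, pos, ha="center", fontsize=9)
    ax.annotate("indirect a*b = " + _lab("indirect"), (0.5, 0.95),
                ha="center", fontsize=9)
    ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def fit_mediation(trials: pd.DataFrame, config: MediationConfig | None = None,
                  seed: int = 0) -> MediationResult:
    """Functional wrapper over :class:`MultilevelMediation`."""
    est = MultilevelMediation(config=config, random_state=seed)
    return est.fit(trials).result_
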