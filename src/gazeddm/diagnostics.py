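"""Posterior predictive checks, parameter recovery and model comparison.

The posterior predictive check replays each trial's empirical dwell shares
(the fitted likelihood conditions on gaze), draws parameter vectors from the
participant-level posterior, forward-simulates replica datasets, and checks
whether empirical RT quantiles (0.1, 0.3, 0.5, 0.7, 0.9, per condition and
choice type) and choice proportions fall inside the 95% highest-density
intervals of the simulated statistics.

The recovery study runs generate -> preprocess -> fit end to end against the
truth sidecar; the model-comparison table ranks fits of one dataset by DIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import FitResult, HierarchicalDDM, MCMCConfig, _hdi
from .likelihood import TrialArrays, _vd_core
from .models import softplus, probit
from .preprocess import dwell_shares, filter_rts, orient_trials
from .synthetic import CohortConfig, gen_dataset
from .wiener import simulate_constant_drift

__all__ = [
    "PPCReport",
    "RecoveryReport",
    "posterior_predictive",
    "recovery_study",
    "compare_models",
    "prepare_trials",
]

RT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)
_CANONICAL = ("alpha", "ndt", "d", "omega", "beta", "theta", "phi_t", "phi_h")


def prepare_trials(trials: pd.DataFrame, fixations: pd.DataFrame):
    """Standard preprocessing chain: RT filter, dwell shares, orientation.

    Returns the oriented modeling table (zero-dwell trials dropped) and a
    report dict.
    """
    kept, report = filter_rts(trials)
    shares = dwell_shares(fixations,
                          labels=("a_taste", "a_health", "b_taste", "b_health"))
    merged = kept.merge(shares, on=["participant", "condition", "trial"], how="inner")
    n_zero = int(merged["zero_dwell"].sum())
    merged = merged[~merged["zero_dwell"]]
    report["n_removed_zero_dwell"] = n_zero
    return orient_trials(merged), report


def _participant_trial_params(fit: FitResult, data: TrialArrays, draw_b, draw_c):
    """Per-trial constrained parameter arrays from one posterior draw."""
    names = fit.param_names
    # expand per trial: baseline for sated, baseline+change for hungry
    out = {}
    idx = data.participant
    for k, name in enumerate(names):
        per_trial = np.where(data.hungry, (draw_b[:, k] + draw_c[:, k])[idx],
                             draw_b[:, k][idx])
        if name in ("alpha", "ndt"):
            per_trial = softplus(per_trial)
        elif name in ("omega", "beta"):
            per_trial = probit(per_trial)
        if name == "phi":
            out["phi_t"] = out["phi_h"] = per_trial
        else:
            out[name] = per_trial
    spec = fit.spec
    defaults = {"beta": 0.5, "theta": 1.0, "phi_t": 1.0, "phi_h": 1.0}
    defaults.update(spec.fixed)
    for name in _CANONICAL:
        out.setdefault(name, np.full(data.n_trials, defaults.get(name, 0.0)))
    return out


def _replica_stats(rt, upper, hungry):
    """The tracked statistics of one (simulated or empirical) dataset."""
    stats = {}
    for cond, mask in (("sated", ~hungry), ("hungry", hungry)):
        stats[(cond, "choice", "p_tasty")] = upper[mask].mean() if mask.any() else np.nan
        for label, cmask in (("tasty", upper), ("healthy", ~upper)):
            sel = mask & cmask
            if sel.sum() >= 2:
                qs = np.quantile(rt[sel], RT_QUANTILES)
            else:
                qs = np.full(len(RT_QUANTILES), np.nan)
            for q, val in zip(RT_QUANTILES, qs):
                stats[(cond, label, f"q{q:.1f}")] = val
    return stats


@dataclass
class PPCReport:
    stats: pd.DataFrame          # empirical value, HDI bounds, inside flag
    n_draws: int
    coverage: float              # fraction of tracked statistics inside HDI

    def flagged(self) -> pd.DataFrame:
        return self.stats[~self.stats["inside"]]


def posterior_predictive(fit: FitResult, trials, n_draws: int = 1000, seed: int = 0,
                         dt: float = 2.5e-3, force: bool = False) -> PPCReport:
    """Simulate replica datasets from the posterior and check HDI coverage.

    Gaze is replayed: each replica trial uses the empirical dwell shares, so
    the simulated drift is the trial's averaged drift under the drawn
    parameters.  RTs are simulated by Euler-Maruyama with bridge-corrected
    absorption.
    """
    if not fit.converged and not force:
        raise RuntimeError("fit did not converge; pass force=True to override")
    if n_draws == 1:
        warnings.warn("n_draws=1 gives degenerate (point) intervals", stacklevel=2)
    data = trials if isinstance(trials, TrialArrays) else TrialArrays.from_frame(trials)
    rng = np.random.default_rng(seed)
    b_all = fit.stacked("baseline")
    c_all = fit.stacked("change")
    pick = rng.integers(0, b_all.shape[0], size=n_draws)

    # one big batched simulation over draws x trials
    cols = {k: [] for k in ("v", "alpha", "beta", "ndt")}
    for s in pick:
        p = _participant_trial_params(fit, data, b_all[s], c_all[s])
        vd = _vd_core(*data.values, *data.dwell,
                      p["omega"], p["theta"], p["phi_t"], p["phi_h"])
        cols["v"].append(p["d"] * vd)
        cols["alpha"].append(p["alpha"])
        cols["beta"].append(p["beta"])
        cols["ndt"].append(p["ndt"])
    flat = {k: np.concatenate(v) for k, v in cols.items()}
    upper_all, rt_all = simulate_constant_drift(
        flat["v"], flat["alpha"], flat["beta"], flat["ndt"], rng, dt=dt)
    upper_all = upper_all.reshape(n_draws, data.n_trials)
    rt_all = rt_all.reshape(n_draws, data.n_trials)
    rows = []
    sim_stats = [_replica_stats(rt_all[s], upper_all[s], data.hungry)
                 for s in range(n_draws)]

    emp = _replica_stats(data.rt, data.choice_tasty, data.hungry)
    keys = list(emp)
    for key in keys:
        draws = np.array([s[key] for s in sim_stats], dtype=float)
        draws = draws[np.isfinite(draws)]
        if draws.size == 0 or not np.isfinite(emp[key]):
            continue
        lo, hi = _hdi(draws, 0.95)
        rows.append({"condition": key[0], "choice_type": key[1], "stat": key[2],
                     "empirical": emp[key], "hdi_2.5": lo, "hdi_97.5": hi,
                     "inside": bool(lo <= emp[key] <= hi)})
    stats = pd.DataFrame(rows)
    return PPCReport(stats=stats, n_draws=n_draws,
                     coverage=float(stats["inside"].mean()))


@dataclass
class RecoveryReport:
    params: pd.DataFrame         # per parameter: correlation, truth-in-interval
    fit: FitResult
    truth_group: pd.DataFrame    # group-level truths vs posterior HDIs

    def correlation(self, param: str) -> float:
        return float(self.params.set_index("parameter").loc[param, "correlation"])


def recovery_study(model: str, cohort: CohortConfig | None = None,
                   fit_config: MCMCConfig | None = None, seed: int = 0) -> RecoveryReport:
    """End-to-end generate -> preprocess -> fit -> compare-to-truth."""
    cfg = cohort or CohortConfig(model=model)
    cfg.model = model
    trials, fixations, _, truth = gen_dataset(cfg, seed=seed)
    oriented, _ = prepare_trials(trials, fixations)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = HierarchicalDDM(model=model, config=fit_config,
                              random_state=seed + 1).fit(oriented).result_

    spec = fit.spec
    names = list(fit.param_names)
    b_hat, c_hat = fit.participant_raw_means()
    true_b = truth.participant_baseline_raw
    true_c = truth.participant_change_raw

    def _constrained(frame, name):
        if name == "phi":
            x = frame["phi_t"].to_numpy() if "phi_t" in frame else frame["phi"].to_numpy()
        else:
            x = frame[name].to_numpy()
        if name in ("alpha", "ndt"):
            return np.asarray(softplus(x))
        if name in ("omega", "beta"):
            return np.asarray(probit(x))
        return x

    rows = []
    for name in names:
        est_pairs = np.concatenate([
            _constrained(b_hat, name),
            _constrained(b_hat + c_hat, name)])
        if name == "phi":
            tb = true_b["phi_t"].to_numpy()
            tc = true_c["phi_t"].to_numpy()
        elif name == "beta":
            tb = np.full(len(true_b), 0.0)   # generator fixes beta at 0.5 (raw 0)
            tc = np.zeros(len(true_c))
        else:
            tb = true_b[name].to_numpy()
            tc = true_c[name].to_numpy()
        tr_pairs = np.concatenate([
            _constrained(pd.DataFrame({name: tb}), name),
            _constrained(pd.DataFrame({name: tb + tc}), name)])
        r = np.corrcoef(tr_pairs, est_pairs)[0, 1] if np.std(tr_pairs) > 0 else np.nan
        rows.append({"parameter": name, "correlation": float(r)})
    params = pd.DataFrame(rows)

    # group-level: is the generating group mean inside the 95% HDI?
    gp = fit.group_posterior()
    g_rows = []
    gt = truth.group
    for name in names:
        src = "phi_t" if name == "phi" else name
        if name == "beta":
            t_sated = t_hungry = 0.5
        else:
            t_sated = _constrained(pd.DataFrame({name: [gt.baseline_mean[src]]}), name)[0]
            t_hungry = _constrained(pd.DataFrame(
                {name: [gt.baseline_mean[src] + gt.change_mean[src]]}), name)[0]
        for cond, t in (("sated", t_sated), ("hungry", t_hungry)):
            row = gp[(gp.parameter == name) & (gp.condition == cond)].iloc[0]
            g_rows.append({"parameter": name, "condition": cond, "truth": float(t),
                           "hdi_2.5": row["hdi_2.5"], "hdi_97.5": row["hdi_97.5"],
                           "inside": bool(row["hdi_2.5"] <= t <= row["hdi_97.5"])})
    return RecoveryReport(params=params, fit=fit, truth_group=pd.DataFrame(g_rows))


def plot_ppc_quantiles(report: PPCReport, path=None):
    """Condition-colored RT-quantile plot with HDI whiskers.

    Empirical quantiles as points, posterior predictive 95% HDIs as vertical
    bars, one panel per choice type.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"sated": "tab:blue", "hungry": "tab:orange"}
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, ct in zip(axes, ("tasty", "healthy")):
        for cond in ("sated", "hungry"):
            sub = report.stats[(report.stats.condition == cond)
                               & (report.stats.choice_type == ct)].sort_values("stat")
            q = [float(s[1:]) for s in sub["stat"]]
            ax.vlines(q, sub["hdi_2.5"], sub["hdi_97.5"], color=colors[cond],
                      alpha=0.6, lw=4, label=f"{cond} 95% HDI")
            ax.plot(q, sub["empirical"], "o-", color=colors[cond],
                    label=f"{cond} empirical")
        ax.set_title(f"{ct} choices")
        ax.set_xlabel("RT quantile")
    axes[0].set_ylabel("RT (s)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """DIC table over fits of the same dataset; best model marked."""
    if not fits:
        raise ValueError("no fits given")
    prints = {f.dataset_fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError(f"fits come from different datasets: {sorted(prints)}")
    rows = []
    for f in fits:
        rows.append({"model": f.model,
                     "parameters": "+".join(f.param_names),
                     "dic": f.dic, "p_d": f.p_d, "max_rhat": f.max_rhat})
    tbl = pd.DataFrame(rows).sort_values("dic").reset_index(drop=True)
    tbl["delta_dic"] = tbl["dic"] - tbl["dic"].min()
    tbl["best"] = tbl["delta_dic"] == 0.0
    return tbl
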