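"""Synthetic cohort generator with known ground truth.

Emulates the study design end to end: a 66-item food catalog spread over the
five Nutri-Score classes, slider ratings (0–100) with a two-factor structure
(taste/wanting vs. health/calories), per-trial 4-AOI fixation streams with a
condition-dependent bias toward food images over score labels, and binary
choices plus RTs produced by forward simulation of the gaze-weighted
diffusion model with condition-shifted parameters.

Gaze is exogenous: fixation streams are generated independently of the
accumulating evidence, matching the fitted model's treatment of dwell as
given.  Each trial's RT comes first from the diffusion sample under the
piecewise gaze-drift schedule; the stream is then truncated (or its last
fixation extended) to span exactly the decision time so that dwell shares
are well defined.

A ``TruthSidecar`` records every generating parameter; inference code never
reads it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .models import (constrain_params, inv_softplus, model_registry,
                     scale_values)
from .wiener import simulate_piecewise

__all__ = [
    "GazeParams",
    "RatingFactorParams",
    "GroupTruth",
    "CohortConfig",
    "TruthSidecar",
    "gen_items",
    "gen_ratings",
    "gen_fixations",
    "gen_dataset",
]

NUTRI_CLASSES = ("A", "B", "C", "D", "E")
DEFAULT_CLASS_COUNTS = {"A": 13, "B": 13, "C": 12, "D": 14, "E": 14}
CONDITIONS = ("sated", "hungry")


@dataclass
class GazeParams:
    """Exogenous gaze process: image-vs-score bias and dwell durations.

    ``p_image`` is the per-condition probability that a fixation lands on a
    food image (taste attribute) rather than a score label; the option being
    fixated alternates.  Dwell durations are log-normal with the given mean
    (seconds) and log-scale shape.
    """

    p_image: dict = field(default_factory=lambda: {"sated": 0.80, "hungry": 0.85})
    dwell_mean: float = 0.35
    dwell_sigma: float = 0.45

    def validate(self):
        for cond, p in self.p_image.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_image[{cond}]={p} outside [0, 1]")
        if self.dwell_mean <= 0 or self.dwell_sigma <= 0:
            raise ValueError("dwell parameters must be positive")


@dataclass
class RatingFactorParams:
    """Two near-orthogonal latent factors drive the six item measures.

    Factor 1 (palatability) loads on taste and wanting; factor 2 (healthiness)
    loads positively on the health rating and the Nutri-Score and negatively
    on both calorie measures.  ``noise_sd`` is rater noise on the 0–100 scale.
    """

    taste_loading: float = 18.0
    wanting_loading: float = 16.0
    health_loading: float = 20.0
    calorie_loading: float = -17.0
    noise_sd: float = 8.0
    participant_sd: float = 5.0   # participant-specific item taste twist

    def validate(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


#: group-level truths on the raw (unconstrained) scale; ``change`` shifts the
#: hungry condition additively before transformation.
@dataclass
class GroupTruth:
    baseline_mean: dict = field(default_factory=lambda: {
        "alpha": float(inv_softplus(2.2)), "ndt": float(inv_softplus(0.35)),
        "d": 0.06, "omega": 0.739, "theta": 0.8, "phi_t": 0.9, "phi_h": 0.8,
    })
    baseline_sd: dict = field(default_factory=lambda: {
        "alpha": 0.3, "ndt": 0.15, "d": 0.015, "omega": 0.3,
        "theta": 0.1, "phi_t": 0.1, "phi_h": 0.15,
    })
    change_mean: dict = field(default_factory=lambda: {
        "alpha": 0.0, "ndt": 0.0, "d": 0.0, "omega": 0.3,
        "theta": 0.0, "phi_t": 0.0, "phi_h": -0.35,
    })
    change_sd: dict = field(default_factory=lambda: {
        "alpha": 0.1, "ndt": 0.05, "d": 0.01, "omega": 0.15,
        "theta": 0.05, "phi_t": 0.05, "phi_h": 0.1,
    })


@dataclass
class CohortConfig:
    model: str = "maaDDM2phi"
    n_participants: int = 70
    n_trials: int = 190
    n_items: int = 66
    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    conflict_fraction: float = 0.4
    truth: GroupTruth = field(default_factory=GroupTruth)
    gaze: GazeParams = field(default_factory=GazeParams)
    ratings: RatingFactorParams = field(default_factory=RatingFactorParams)
    dt: float = 1e-3
    gaze_horizon: float = 20.0    # seconds of pre-generated fixations per trial


@dataclass
class TruthSidecar:
    """Generating parameters, stored alongside the data; never used to fit."""

    model: str
    participant_baseline_raw: pd.DataFrame
    participant_change_raw: pd.DataFrame
    group: GroupTruth
    gaze: GazeParams
    ratings: RatingFactorParams

    def to_json(self) -> str:
        return json.dumps({
            "model": self.model,
            "participant_baseline_raw": self.participant_baseline_raw.to_dict("list"),
            "participant_change_raw": self.participant_change_raw.to_dict("list"),
            "group": asdict(self.group),
            "gaze": asdict(self.gaze),
            "ratings": asdict(self.ratings),
        }, indent=1)


def gen_items(n_items: int = 66, class_counts: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Item catalog: ids, Nutri-Score class, sweet/savory tag, objective kcal."""
    class_counts = dict(DEFAULT_CLASS_COUNTS) if class_counts is None else dict(class_counts)
    if sum(class_counts.values()) != n_items:
        raise ValueError(f"class counts sum to {sum(class_counts.values())}, expected {n_items}")
    rng = np.random.default_rng(seed)
    classes = [c for c, n in sorted(class_counts.items()) for _ in range(n)]
    # latent healthiness decreases from class A to E
    class_rank = {c: i for i, c in enumerate(NUTRI_CLASSES)}
    h_latent = np.array([1.2 - 0.6 * class_rank.get(c, 2) for c in classes])
    h_latent = h_latent + rng.normal(0, 0.15, size=n_items)
    kcal = np.clip(250.0 - 70.0 * h_latent + rng.normal(0, 25.0, size=n_items), 20.0, None)
    sweet = rng.random(n_items) < 0.5
    return pd.DataFrame({
        "item_id": np.arange(n_items),
        "nutri_class": classes,
        "sweet_savory": np.where(sweet, "sweet", "savory"),
        "health_latent": h_latent,
        "taste_latent": rng.normal(0, 1, size=n_items),
        "kcal": kcal,
    })


def gen_ratings(catalog: pd.DataFrame, n_participants: int = 70,
                factor_params: RatingFactorParams | None = None, seed: int = 0) -> pd.DataFrame:
    """Per participant × item slider ratings (0–100) with a two-factor structure."""
    fp = factor_params or RatingFactorParams()
    fp.validate()
    rng = np.random.default_rng(seed)
    n_items = len(catalog)
    t = catalog["taste_latent"].to_numpy()
    h = catalog["health_latent"].to_numpy()
    rows = []
    for p in range(n_participants):
        t_p = t + rng.normal(0, fp.participant_sd / 20.0, size=n_items)
        noise = lambda: rng.normal(0, fp.noise_sd, size=n_items)
        rows.append(pd.DataFrame({
            "participant": p,
            "item_id": catalog["item_id"].to_numpy(),
            "taste": np.clip(50 + fp.taste_loading * t_p + noise(), 0, 100),
            "wanting": np.clip(50 + fp.wanting_loading * t_p + noise(), 0, 100),
            "health": np.clip(50 + fp.health_loading * h + noise(), 0, 100),
            "calorie": np.clip(50 + fp.calorie_loading * h + noise(), 0, 100),
        }))
    return pd.concat(rows, ignore_index=True)


def gen_fixations(n_fixations: int, condition: str, gaze_params: GazeParams,
                  rng: np.random.Generator):
    """One stream of alternating-option fixations: (aoi labels, durations s)."""
    gaze_params.validate()
    p_img = gaze_params.p_image[condition]
    start = int(rng.random() < 0.5)
    opt = np.where((np.arange(n_fixations) + start) % 2 == 0, "i", "j")
    attr = np.where(rng.random(n_fixations) < p_img, "taste", "health")
    aois = np.char.add(np.char.add(opt, "_"), attr)
    mu = np.log(gaze_params.dwell_mean) - gaze_params.dwell_sigma**2 / 2.0
    durations = rng.lognormal(mu, gaze_params.dwell_sigma, size=n_fixations)
    return aois, durations


_AOI_COL = {"i_taste": 0, "i_health": 1, "j_taste": 2, "j_health": 3}


def _select_pairs(scaled: pd.DataFrame, n_trials: int, frac: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Item pairs for one participant-session with a target conflict fraction."""
    t = scaled["taste"].to_numpy()
    h = scaled["health"].to_numpy()
    ids = scaled["item_id"].to_numpy()
    ii, jj = np.triu_indices(len(ids), k=1)
    conflict = ((t[ii] > t[jj]) & (h[ii] < h[jj])) | ((t[jj] > t[ii]) & (h[jj] < h[ii]))
    n_conf = int(round(frac * n_trials))
    pool_c = np.flatnonzero(conflict)
    pool_n = np.flatnonzero(~conflict)
    n_conf = min(n_conf, n_trials) if pool_n.size else n_trials
    pick_c = rng.choice(pool_c, size=min(n_conf, n_trials), replace=True) if pool_c.size else np.empty(0, int)
    pick_n = rng.choice(pool_n, size=n_trials - pick_c.size, replace=True) if pool_n.size else np.empty(0, int)
    picks = np.concatenate([pick_c, pick_n])
    rng.shuffle(picks)
    return np.column_stack([ids[ii[picks]], ids[jj[picks]]])


def gen_dataset(config: CohortConfig | None = None, seed: int = 0):
    """Full synthetic dataset: (trials, fixations, ratings, TruthSidecar).

    Trials are emitted in screen coordinates (options ``a``/``b`` with random
    orientation, ``choice`` in {a, b}, raw RT in seconds); fixation events
    carry screen AOI labels (``a_taste`` ...) and durations in ms, already
    truncated to each trial's decision time.  Preprocessing reconstructs the
    model's oriented view.
    """
    cfg = config or CohortConfig()
    spec = model_registry(cfg.model)
    truth_names = list(cfg.truth.baseline_mean)
    missing = [p for p in spec.estimated if p not in truth_names and p != "phi"]
    if missing and "phi" not in spec.estimated:
        raise ValueError(f"truth lacks parameters {missing} required by {cfg.model}")
    rng = np.random.default_rng(seed)

    catalog = gen_items(cfg.n_items, cfg.class_counts, seed=rng.integers(2**31))
    ratings = gen_ratings(catalog, cfg.n_participants, cfg.ratings, seed=rng.integers(2**31))
    scaled = scale_values(ratings, ["taste", "health"], by="participant")

    # participant-level truths (raw scale)
    gt = cfg.truth
    base = {p: rng.normal(gt.baseline_mean[p], gt.baseline_sd[p], cfg.n_participants)
            for p in truth_names}
    change = {p: rng.normal(gt.change_mean[p], gt.change_sd[p], cfg.n_participants)
              for p in truth_names}

    trial_rows, fix_rows = [], []
    for p in range(cfg.n_participants):
        sc = scaled[scaled["participant"] == p].set_index("item_id")
        for cond in CONDITIONS:
            raw = {k: base[k][p] + (change[k][p] if cond == "hungry" else 0.0)
                   for k in truth_names}
            if "phi" in spec.estimated:
                raw = dict(raw)
                raw["phi"] = raw.pop("phi_t")
                raw.pop("phi_h", None)
            raw = {k: v for k, v in raw.items() if k in spec.estimated}
            params = constrain_params(spec, raw)

            pairs = _select_pairs(sc.reset_index(), cfg.n_trials, cfg.conflict_fraction, rng)
            # orient: option i = larger scaled taste (ties by item id)
            t1 = sc.loc[pairs[:, 0], "taste"].to_numpy()
            t2 = sc.loc[pairs[:, 1], "taste"].to_numpy()
            first_is_i = (t1 > t2) | ((t1 == t2) & (pairs[:, 0] < pairs[:, 1]))
            item_i = np.where(first_is_i, pairs[:, 0], pairs[:, 1])
            item_j = np.where(first_is_i, pairs[:, 1], pairs[:, 0])
            vals = (sc.loc[item_i, "taste"].to_numpy(), sc.loc[item_j, "taste"].to_numpy(),
                    sc.loc[item_i, "health"].to_numpy(), sc.loc[item_j, "health"].to_numpy())

            # exogenous gaze streams, then piecewise-drift simulation
            n_fix = max(8, int(np.ceil(cfg.gaze_horizon / cfg.gaze.dwell_mean * 1.5)))
            streams = [gen_fixations(n_fix, cond, cfg.gaze, rng) for _ in range(cfg.n_trials)]
            from .models import value_difference  # local to avoid cycle at import
            # drift while fixating AOI m is d * VD with a one-hot dwell vector;
            # precompute the four per-AOI VDs for every trial at once
            eye = np.eye(4)
            vd4 = np.stack([value_difference(spec, params, vals, tuple(eye[m]))
                            for m in range(4)], axis=1)      # (n_trials, 4)
            drifts, durs, offsets = [], [], [0]
            for k, (aois, ds) in enumerate(streams):
                codes = np.array([_AOI_COL[a] for a in aois])
                drifts.append(params.d * vd4[k, codes])
                durs.append(ds)
                offsets.append(offsets[-1] + len(aois))
            upper, rt, dtime = simulate_piecewise(
                np.concatenate(drifts), np.concatenate(durs), np.array(offsets),
                params.alpha, params.beta, params.ndt,
                rng, dt=cfg.dt)

            # truncate/extend streams to the decision time; map i/j -> screen a/b
            i_is_a = rng.random(cfg.n_trials) < 0.5
            for k, (aois, ds) in enumerate(streams):
                cum = np.cumsum(ds)
                n_keep = int(np.searchsorted(cum, dtime[k]) + 1)
                n_keep = min(n_keep, len(ds))
                kept = ds[:n_keep].copy()
                kept[-1] -= max(cum[n_keep - 1] - dtime[k], 0.0)
                if n_keep == len(ds) and cum[-1] < dtime[k]:
                    kept[-1] += dtime[k] - cum[-1]     # extend final fixation
                kept = np.maximum(kept, 1e-6)
                swap = {"i": "a", "j": "b"} if i_is_a[k] else {"i": "b", "j": "a"}
                screen_aoi = [swap[a[0]] + a[1:] for a in aois[:n_keep]]
                fix_rows.append(pd.DataFrame({
                    "participant": p, "condition": cond, "trial": k,
                    "aoi": screen_aoi, "duration": kept * 1000.0,
                }))
            chose_i = upper
            trial_rows.append(pd.DataFrame({
                "participant": p, "condition": cond, "trial": np.arange(cfg.n_trials),
                "item_a": np.where(i_is_a, item_i, item_j),
                "item_b": np.where(i_is_a, item_j, item_i),
                "taste_a": np.where(i_is_a, vals[0], vals[1]),
                "taste_b": np.where(i_is_a, vals[1], vals[0]),
                "health_a": np.where(i_is_a, vals[2], vals[3]),
                "health_b": np.where(i_is_a, vals[3], vals[2]),
                "choice": np.where(chose_i == i_is_a, "a", "b"),
                "rt": rt,
            }))

    trials = pd.concat(trial_rows, ignore_index=True)
    fixations = pd.concat(fix_rows, ignore_index=True)
    sidecar = TruthSidecar(
        model=cfg.model,
        participant_baseline_raw=pd.DataFrame(base),
        participant_change_raw=pd.DataFrame(change),
        group=gt, gaze=cfg.gaze, ratings=cfg.ratings,
    )
    return trials, fixations, ratings, sidecar
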