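"""Trial exclusion, conflict labeling and eye-tracking aggregation.

Input tables are long-format pandas DataFrames:

* trials — one row per choice with ``participant, condition, trial`` keys,
  attribute values for the two screen options (``taste_a/taste_b`` etc.),
  ``choice`` (``"a"``/``"b"``) and ``rt`` in seconds;
* fixations — one row per fixation event with the trial key, either an
  ``aoi`` label in ``{i_taste, i_health, j_taste, j_health, none}`` (or the
  un-oriented ``{a_taste, ...}``) or raw ``x, y`` screen coordinates, and a
  positive ``duration`` in milliseconds.

All rules operate per participant × condition.  RT exclusion removes trials
faster than 250 ms (strict) or slower than the group's pre-exclusion
mean + 4 SD; both statistics are computed on the unfiltered group, in a
single pass.  A conflict trial is one where one option is strictly tastier
and strictly less healthy than the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AOILayout",
    "filter_rts",
    "label_conflict",
    "assign_aoi",
    "dwell_shares",
    "orient_trials",
]

RT_FLOOR = 0.250   # seconds, strict
RT_SD_MULT = 4.0

AOI_LABELS = ("a_taste", "a_health", "b_taste", "b_health")


@dataclass
class AOILayout:
    """Four screen rectangles (left, top, width, height in pixels) per AOI.

    ``inflation`` enlarges width and height by that fraction about each
    rectangle's center before point-in-rectangle tests (default 5%).
    Default geometry: two option columns, food image (387.2 x 259.2 px)
    stacked with its score label (166.5 x 94.1 px) on a 1024 x 768 screen.
    """

    rects: dict[str, tuple[float, float, float, float]] = field(default_factory=lambda: {
        "a_taste": (70.0, 180.0, 387.2, 259.2),
        "a_health": (180.0, 500.0, 166.5, 94.1),
        "b_taste": (566.0, 180.0, 387.2, 259.2),
        "b_health": (676.0, 500.0, 166.5, 94.1),
    })
    inflation: float = 0.05

    def inflated(self) -> dict[str, tuple[float, float, float, float]]:
        out = {}
        for name, (left, top, w, h) in self.rects.items():
            dw, dh = w * self.inflation, h * self.inflation
            out[name] = (left - dw / 2, top - dh / 2, w + dw, h + dh)
        return out

    def validate(self) -> None:
        infl = list(self.inflated().items())
        for i, (na, ra) in enumerate(infl):
            for nb, rb in infl[i + 1:]:
                if (ra[0] < rb[0] + rb[2] and rb[0] < ra[0] + ra[2]
                        and ra[1] < rb[1] + rb[3] and rb[1] < ra[1] + ra[3]):
                    raise ValueError(f"inflated AOIs {na} and {nb} overlap; assignment ambiguous")


def filter_rts(trials: pd.DataFrame, rt_col: str = "rt",
               group_cols: tuple[str, str] = ("participant", "condition")):
    """Apply the per-group RT exclusion rules; return (retained, report).

    Removes trials with ``rt < 0.250 s`` or ``rt > mean + 4*SD`` where mean/SD
    are computed per participant × condition on the pre-exclusion trials.
    Groups with a single trial skip the SD rule (with a warning); the floor
    rule still applies.
    """
    trials = trials.copy()
    fast = trials[rt_col].to_numpy() < RT_FLOOR
    slow = np.zeros(len(trials), dtype=bool)
    for _, idx in trials.groupby(list(group_cols)).groups.items():
        rts = trials.loc[idx, rt_col].to_numpy()
        if rts.size < 2:
            warnings.warn("single-trial group: SD rule skipped", stacklevel=2)
            continue
        mean, sd = rts.mean(), rts.std(ddof=1)
        slow[trials.index.get_indexer(idx)] = rts > mean + RT_SD_MULT * sd
    keep = ~(fast | slow)
    report = {
        "n_input": int(len(trials)),
        "n_removed_fast": int(fast.sum()),
        "n_removed_slow": int((slow & ~fast).sum()),
        "n_retained": int(keep.sum()),
    }
    return trials.loc[keep], report


def label_conflict(trials: pd.DataFrame,
                   taste_cols: tuple[str, str] = ("taste_a", "taste_b"),
                   health_cols: tuple[str, str] = ("health_a", "health_b")) -> pd.DataFrame:
    """Flag conflict trials (one option strictly tastier and strictly less healthy).

    Ties on either attribute are not conflicts.  Trials with missing attribute
    values get ``conflict = False`` and ``conflict_valid = False``.
    """
    t_a = trials[taste_cols[0]].to_numpy(dtype=float)
    t_b = trials[taste_cols[1]].to_numpy(dtype=float)
    h_a = trials[health_cols[0]].to_numpy(dtype=float)
    h_b = trials[health_cols[1]].to_numpy(dtype=float)
    valid = np.isfinite(t_a) & np.isfinite(t_b) & np.isfinite(h_a) & np.isfinite(h_b)
    conflict = ((t_a > t_b) & (h_a < h_b)) | ((t_b > t_a) & (h_b < h_a))
    out = trials.copy()
    out["conflict"] = conflict & valid
    out["conflict_valid"] = valid
    return out


def assign_aoi(fixations: pd.DataFrame, layout: AOILayout,
               x_col: str = "x", y_col: str = "y") -> pd.DataFrame:
    """Label fixation points with the inflated AOI containing them (else ``none``)."""
    layout.validate()
    x = fixations[x_col].to_numpy(dtype=float)
    y = fixations[y_col].to_numpy(dtype=float)
    label = np.full(len(fixations), "none", dtype=object)
    for name, (left, top, w, h) in layout.inflated().items():
        inside = (x >= left) & (x <= left + w) & (y >= top) & (y <= top + h)
        label[inside] = name
    out = fixations.copy()
    out["aoi"] = label
    return out


def dwell_shares(fixations: pd.DataFrame,
                 trial_cols: tuple[str, ...] = ("participant", "condition", "trial"),
                 labels: tuple[str, ...] = AOI_LABELS) -> pd.DataFrame:
    """Per-trial relative dwell on the four AOIs (``none`` time ignored).

    Returns one row per trial with share columns ``f_<label>`` summing to 1.
    Trials whose total AOI dwell is zero are flagged ``zero_dwell = True``
    (shares NaN); the likelihood cannot use them and they are dropped from
    fitting upstream.
    """
    fx = fixations[fixations["aoi"].isin(labels)]
    sums = (fx.groupby(list(trial_cols) + ["aoi"], observed=False)["duration"].sum()
            .unstack("aoi", fill_value=0.0).reindex(columns=list(labels), fill_value=0.0))
    all_trials = fixations[list(trial_cols)].drop_duplicates().set_index(list(trial_cols))
    sums = sums.reindex(all_trials.index, fill_value=0.0)
    total = sums.sum(axis=1)
    shares = sums.div(total, axis=0)
    shares.columns = [f"f_{c}" for c in shares.columns]
    shares["zero_dwell"] = total.to_numpy() == 0
    return shares.reset_index()


def orient_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Re-express screen options (a, b) in model coordinates (i = tasty option).

    Option *i* is the option with the larger scaled taste value; exact taste
    ties assign *i* by option-id order (reported via ``tie_broken``).  Output
    columns: ``taste_i, taste_j, health_i, health_j``, dwell shares
    ``f_it, f_ih, f_jt, f_jh`` and ``choice_tasty`` (chose option i).
    """
    a_tasty = trials["taste_a"].to_numpy() > trials["taste_b"].to_numpy()
    tie = trials["taste_a"].to_numpy() == trials["taste_b"].to_numpy()
    if "item_a" in trials.columns:
        a_first = trials["item_a"].to_numpy() <= trials["item_b"].to_numpy()
    else:
        a_first = np.ones(len(trials), dtype=bool)
    i_is_a = np.where(tie, a_first, a_tasty)
    out = trials.copy()
    for attr in ("taste", "health"):
        out[f"{attr}_i"] = np.where(i_is_a, trials[f"{attr}_a"], trials[f"{attr}_b"])
        out[f"{attr}_j"] = np.where(i_is_a, trials[f"{attr}_b"], trials[f"{attr}_a"])
    share_map = {"f_it": ("f_a_taste", "f_b_taste"), "f_ih": ("f_a_health", "f_b_health"),
                 "f_jt": ("f_b_taste", "f_a_taste"), "f_jh": ("f_b_health", "f_a_health")}
    for new, (col_a, col_b) in share_map.items():
        if col_a in trials.columns:
            out[new] = np.where(i_is_a, trials[col_a], trials[col_b])
    out["choice_tasty"] = np.where(i_is_a, trials["choice"].eq("a"), trials["choice"].eq("b"))
    out["tie_broken"] = tie
    return out
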