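"""RT exclusion, conflict labeling, AOI assignment and dwell aggregation."""

import numpy as np
import pandas as pd
import pytest

from gazeddm.preprocess import (AOILayout, assign_aoi, dwell_shares, filter_rts,
                                label_conflict, orient_trials)


def _trials(rts, participant=1, condition="sated"):
    return pd.DataFrame({"participant": participant, "condition": condition,
                         "trial": range(len(rts)), "rt": rts})


class TestFilterRts:
    def test_fast_floor_is_strict(self):
        trials = _trials([0.2, 1.0, 1.0, 1.0, 1.0])
        kept, report = filter_rts(trials)
        assert len(kept) == 4 and report["n_removed_fast"] == 1
        # exactly 250 ms is retained
        kept2, _ = filter_rts(_trials([0.250, 1.0, 1.0]))
        assert len(kept2) == 3

    def test_sd_rule_uses_preexclusion_moments(self):
        base = [0.9, 1.1] * 25
        outlier = float(np.mean(base) + 5 * np.std(base, ddof=1))
        trials = _trials(base + [outlier])
        thresh = np.mean(base + [outlier]) + 4 * np.std(base + [outlier], ddof=1)
        assert outlier > thresh  # the fixture really is beyond mean + 4 SD
        kept, report = filter_rts(trials)
        assert len(kept) == 50
        assert report["n_removed_slow"] == 1
        assert outlier not in kept["rt"].to_numpy()

    def test_degenerate_zero_sd_keeps_all(self):
        kept, report = filter_rts(_trials([1.0] * 10))
        assert len(kept) == 10 and report["n_removed_slow"] == 0

    def test_single_trial_group_warns_and_applies_floor_only(self):
        with pytest.warns(UserWarning, match="single-trial"):
            kept, _ = filter_rts(_trials([0.1]))
        assert len(kept) == 0
        with pytest.warns(UserWarning):
            kept2, _ = filter_rts(_trials([1.0]))
        assert len(kept2) == 1

    def test_rule_is_per_participant_per_condition(self):
        a = _trials([1.0] * 20 + [2.5], participant=1)
        b = _trials([2.4] * 21, participant=2)   # 2.5-ish RTs normal here
        kept, _ = filter_rts(pd.concat([a, b], ignore_index=True))
        assert (kept[kept.participant == 2].rt == 2.4).all()
        assert 2.5 not in kept[kept.participant == 1].rt.to_numpy()

    def test_idempotent_on_retained_set(self):
        rng = np.random.default_rng(0)
        trials = _trials(np.abs(rng.normal(1.0, 0.2, 200)) + 0.3)
        kept, _ = filter_rts(trials)
        # moments recomputed on the retained set can only shrink the threshold
        # slightly; the rule referencing pre-exclusion moments removes nothing
        kept2, report2 = filter_rts(kept)
        assert report2["n_removed_fast"] == 0


class TestLabelConflict:
    def _frame(self, ta, tb, ha, hb):
        return pd.DataFrame({"taste_a": [ta], "taste_b": [tb],
                             "health_a": [ha], "health_b": [hb]})

    @pytest.mark.parametrize("ta,tb,ha,hb,expected", [
        (8, 2, 2, 8, True),    # tastier and less healthy
        (2, 8, 8, 2, True),    # symmetric case
        (8, 2, 8, 2, False),   # one option dominates
        (5, 5, 2, 8, False),   # taste tie
        (8, 2, 5, 5, False),   # health tie
    ])
    def test_definition(self, ta, tb, ha, hb, expected):
        out = label_conflict(self._frame(ta, tb, ha, hb))
        assert bool(out["conflict"].iloc[0]) is expected

    def test_missing_values_flagged_invalid(self):
        out = label_conflict(self._frame(8, 2, np.nan, 8))
        assert not out["conflict"].iloc[0]
        assert not out["conflict_valid"].iloc[0]


class TestAssignAoi:
    def test_center_and_background(self):
        layout = AOILayout()
        left, top, w, h = layout.rects["a_taste"]
        fx = pd.DataFrame({"x": [left + w / 2, 5.0], "y": [top + h / 2, 5.0]})
        out = assign_aoi(fx, layout)
        assert list(out["aoi"]) == ["a_taste", "none"]

    def test_inflation_extends_edges(self):
        # a 387.2 x 259.2 px rectangle inflated by 5% grows 9.68 px on the
        # left edge; a point 1% of the width outside the nominal edge
        # (3.872 px) is inside the inflated AOI
        layout = AOILayout()
        left, top, w, h = layout.rects["a_taste"]
        x_out = left - 0.01 * w
        assert x_out < left
        assert x_out > left - 0.025 * w  # within the 9.68 px inflated margin
        out = assign_aoi(pd.DataFrame({"x": [x_out], "y": [top + h / 2]}), layout)
        assert out["aoi"].iloc[0] == "a_taste"

    def test_overlapping_inflated_rects_rejected(self):
        layout = AOILayout(rects={"a_taste": (0, 0, 100, 100),
                                  "a_health": (100, 0, 100, 100),
                                  "b_taste": (0, 300, 100, 100),
                                  "b_health": (300, 300, 100, 100)},
                           inflation=0.05)
        with pytest.raises(ValueError, match="overlap"):
            assign_aoi(pd.DataFrame({"x": [1.0], "y": [1.0]}), layout)


def _fix(aois, durations, trial=0):
    return pd.DataFrame({"participant": 1, "condition": "sated", "trial": trial,
                         "aoi": aois, "duration": durations})


class TestDwellShares:
    def test_single_fixation(self):
        out = dwell_shares(_fix(["a_taste"], [400.0]))
        row = out.iloc[0]
        assert row["f_a_taste"] == 1.0 and row["f_b_health"] == 0.0

    def test_arithmetic(self):
        # dwell sums (200, 100, 100, 0) ms -> shares (0.5, 0.25, 0.25, 0)
        out = dwell_shares(_fix(["a_taste", "a_health", "b_taste"],
                                [200.0, 100.0, 100.0]))
        row = out.iloc[0]
        assert (row["f_a_taste"], row["f_a_health"], row["f_b_taste"],
                row["f_b_health"]) == (0.5, 0.25, 0.25, 0.0)

    def test_none_time_excluded_from_denominator(self):
        out = dwell_shares(_fix(["a_taste", "none"], [200.0, 300.0]))
        assert out.iloc[0]["f_a_taste"] == 1.0

    def test_zero_dwell_trials_flagged(self):
        out = dwell_shares(_fix(["none", "none"], [200.0, 300.0]))
        assert bool(out.iloc[0]["zero_dwell"])

    def test_split_fixation_invariance(self):
        whole = dwell_shares(_fix(["a_taste", "b_health"], [300.0, 100.0]))
        split = dwell_shares(_fix(["a_taste", "a_taste", "b_health"],
                                  [150.0, 150.0, 100.0]))
        cols = ["f_a_taste", "f_a_health", "f_b_taste", "f_b_health"]
        np.testing.assert_allclose(whole[cols].to_numpy(), split[cols].to_numpy())

    def test_shares_sum_to_one(self, rng):
        frames = []
        for t in range(20):
            k = rng.integers(1, 8)
            aois = rng.choice(["a_taste", "a_health", "b_taste", "b_health", "none"], k)
            frames.append(_fix(aois, rng.uniform(50, 500, k), trial=t))
        out = dwell_shares(pd.concat(frames, ignore_index=True))
        valid = out[~out["zero_dwell"]]
        cols = ["f_a_taste", "f_a_health", "f_b_taste", "f_b_health"]
        np.testing.assert_allclose(valid[cols].sum(axis=1), 1.0)


class TestOrientTrials:
    def _base(self, ta, tb, choice="a"):
        return pd.DataFrame({
            "participant": [1], "condition": ["sated"], "trial": [0],
            "item_a": [10], "item_b": [20],
            "taste_a": [ta], "taste_b": [tb], "health_a": [3.0], "health_b": [7.0],
            "f_a_taste": [0.5], "f_a_health": [0.2], "f_b_taste": [0.2],
            "f_b_health": [0.1], "choice": [choice], "rt": [1.0]})

    def test_tastier_option_becomes_i(self):
        out = orient_trials(self._base(8.0, 2.0, choice="a"))
        row = out.iloc[0]
        assert row["taste_i"] == 8.0 and row["taste_j"] == 2.0
        assert row["choice_tasty"]
        assert (row["f_it"], row["f_ih"]) == (0.5, 0.2)

    def test_swap_when_b_is_tastier(self):
        out = orient_trials(self._base(2.0, 8.0, choice="a"))
        row = out.iloc[0]
        assert row["taste_i"] == 8.0
        assert not row["choice_tasty"]          # chose the less tasty option
        assert (row["f_it"], row["f_ih"]) == (0.2, 0.1)

    def test_exact_tie_broken_by_item_id_and_reported(self):
        out = orient_trials(self._base(5.0, 5.0))
        row = out.iloc[0]
        assert row["tie_broken"]
        assert row["taste_i"] == 5.0  # item_a (lower id) chosen as i
        assert row["health_i"] == 3.0
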