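"""Priors, transforms, condition assembly, Rhat, DIC and the sampler contract."""

import numpy as np
import pytest
from scipy.special import ndtr

from gazeddm.inference import (MCMCConfig, PRESETS, assemble_condition_params,
                               build_prior_spec, dic, rhat, transform_params,
                               HierarchicalDDM)
from gazeddm.models import model_registry, softplus


class TestPriorSpec:
    def test_two_discount_model_has_seven_rows_per_block(self):
        spec = build_prior_spec(model_registry("maaDDM2phi"))
        assert len(spec.baseline) == 7 and len(spec.change) == 7
        assert spec.baseline["alpha"] == ((2.0, 1.0), 3.0)
        assert spec.baseline["ndt"] == ((-1.0, 1.0), 1.0)
        assert spec.baseline["omega"] == ((0.0, 0.5), 0.5)
        assert spec.change["alpha"] == ((0.0, 1.0), 1.0)
        assert spec.change["omega"] == ((0.0, 0.25), 0.25)

    def test_plain_ddm_has_four_rows_and_no_discounts(self):
        spec = build_prior_spec(model_registry("DDM"))
        assert set(spec.baseline) == {"alpha", "ndt", "d", "omega"}
        assert "theta" not in spec.baseline

    def test_override_is_local(self):
        spec = build_prior_spec(model_registry("DDM"))
        new = spec.override("baseline", "alpha", mean=(1.0, 2.0))
        assert new.baseline["alpha"] == ((1.0, 2.0), 3.0)
        assert new.baseline["ndt"] == spec.baseline["ndt"]
        assert spec.baseline["alpha"] == ((2.0, 1.0), 3.0)  # original untouched

    def test_prior_predictive_respects_constraints(self, rng):
        """Draws from the hyperpriors, pushed through the transforms, always
        land in the legal parameter regions."""
        spec = model_registry("maaDDM2phi_sp")
        priors = build_prior_spec(spec)
        for _ in range(200):
            raw = {}
            for p, ((m, s), tau) in priors.baseline.items():
                mu = rng.normal(m, s)
                sd = abs(rng.normal(0, tau))
                raw[p] = rng.normal(mu, sd)
            params = transform_params(spec, raw)
            assert params.alpha > 0 and params.ndt >= 0
            assert 0 < params.omega < 1 and 0 < params.beta < 1


class TestConditionAssembly:
    def test_zero_change_gives_identical_conditions(self):
        base = {"alpha": 1.2, "omega": 0.4}
        change = {"alpha": 0.0, "omega": 0.0}
        assert assemble_condition_params(base, change, "hungry") == base

    def test_addition_happens_before_transform(self):
        base = {"omega": 0.5}
        change = {"omega": 0.3}
        hungry = assemble_condition_params(base, change, "hungry")
        assert hungry["omega"] == pytest.approx(0.8)
        assert ndtr(hungry["omega"]) == pytest.approx(0.7881446014166034, abs=1e-10)

    def test_monotone_transform_preserves_ordering(self):
        base = {"alpha": 2.0}
        hungry = assemble_condition_params(base, {"alpha": -0.5}, "hungry")
        assert softplus(hungry["alpha"]) < softplus(base["alpha"])
        assert softplus(hungry["alpha"]) == pytest.approx(float(softplus(1.5)))

    def test_misaligned_blocks_rejected(self):
        with pytest.raises(ValueError, match="same parameters"):
            assemble_condition_params({"alpha": 1.0}, {"omega": 0.1}, "hungry")


class TestRhat:
    def test_same_distribution_converges_to_one(self, rng):
        draws = rng.normal(size=(4, 10000))
        assert rhat(draws) <= 1.01

    def test_offset_chains_flagged(self, rng):
        draws = rng.normal(size=(2, 500))
        draws[1] += 10.0
        assert rhat(draws) > 1.05

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            rhat(rng.normal(size=(1, 100)))

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="zero within-chain"):
            r = rhat(np.ones((2, 100)))
        assert r == 1.0


class TestDic:
    def test_point_mass_posterior_has_zero_penalty(self):
        out = dic(np.full(100, 123.4), 123.4)
        assert out["p_d"] == pytest.approx(0.0)
        assert out["dic"] == pytest.approx(123.4)

    def test_conjugate_normal_mean_oracle(self, rng):
        """y_i ~ N(theta, 1) with a flat-ish prior: posterior is
        N(ybar, 1/n) and the effective number of parameters is 1."""
        n = 50
        y = rng.normal(2.0, 1.0, n)
        ybar = y.mean()
        theta_draws = rng.normal(ybar, np.sqrt(1.0 / n), 40000)
        dev = np.array([np.sum((y - th) ** 2) for th in theta_draws])
        dev = dev + n * np.log(2 * np.pi)
        out = dic(dev, np.sum((y - ybar) ** 2) + n * np.log(2 * np.pi))
        assert out["p_d"] == pytest.approx(1.0, abs=0.05)
        assert out["p_v"] == pytest.approx(1.0, abs=0.1)

    def test_missing_trace_rejected(self):
        with pytest.raises(ValueError):
            dic(np.array([]), 0.0)


class TestSamplerContract:
    def test_presets(self):
        assert PRESETS["paper"].chains == 8
        assert PRESETS["paper"].iterations == 60000
        assert PRESETS["paper"].burn_in == 30000
        assert PRESETS["paper"].thin == 12
        assert PRESETS["paper"].n_draws_per_chain == 2500

    def test_same_seed_identical_draws(self, oriented_small):
        cfg = MCMCConfig(2, 300, 150, 3)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = HierarchicalDDM(model="DDM", config=cfg, random_state=5).fit(oriented_small)
            b = HierarchicalDDM(model="DDM", config=cfg, random_state=5).fit(oriented_small)
        for key in a.result_.draws:
            np.testing.assert_array_equal(a.result_.draws[key], b.result_.draws[key])
        np.testing.assert_array_equal(a.result_.deviance, b.result_.deviance)

    def test_draw_counts_and_rhat_coverage(self, ddm_fit):
        cfg = ddm_fit.config
        assert ddm_fit.draws["mu_baseline"].shape == (
            cfg.chains, cfg.n_draws_per_chain, 4)
        # Rhat reported for every group quantity and every participant value
        for p in ddm_fit.param_names:
            assert f"mu_baseline[{p}]" in ddm_fit.rhat
            assert f"sd_change[{p}]" in ddm_fit.rhat
            for j in range(len(ddm_fit.participant_ids)):
                assert f"baseline[{j},{p}]" in ddm_fit.rhat

    def test_group_posterior_reports_both_scales(self, ddm_fit):
        gp = ddm_fit.group_posterior()
        sated_alpha = gp[(gp.parameter == "alpha") & (gp.condition == "sated")]
        assert float(sated_alpha["mean"].iloc[0]) > 0        # transformed scale
        omega = gp[(gp.parameter == "omega") & (gp.condition == "hungry")]
        assert 0 < float(omega["mean"].iloc[0]) < 1
        change = gp[(gp.parameter == "omega") & (gp.condition == "change")]
        assert abs(float(change["mean"].iloc[0])) < 3.0      # raw scale, around 0

    def test_recovers_group_omega_roughly(self, ddm_fit, small_cohort):
        gp = ddm_fit.group_posterior()
        row = gp[(gp.parameter == "omega") & (gp.condition == "sated")].iloc[0]
        truth = float(ndtr(small_cohort["truth"].group.baseline_mean["omega"]))
        assert row["hdi_2.5"] - 0.15 < truth < row["hdi_97.5"] + 0.15

    def test_save_load_round_trip(self, ddm_fit, tmp_path):
        from gazeddm.inference import FitResult
        ddm_fit.save(tmp_path / "fit")
        back = FitResult.load(tmp_path / "fit")
        assert back.model == ddm_fit.model
        assert back.dic == pytest.approx(ddm_fit.dic)
        np.testing.assert_array_equal(back.draws["baseline"],
                                      ddm_fit.draws["baseline"])

    def test_frozen_change_block_matches_pooled_likelihood(self, oriented_small):
        """With the change block frozen at zero the hungry condition uses the
        baseline parameters: both conditions' likelihoods coincide with a
        pooled single-condition evaluation on identical draws."""
        from gazeddm.inference import build_prior_spec
        import warnings
        spec = model_registry("DDM")
        priors = build_prior_spec(spec)
        for p in list(priors.change):
            priors.change[p] = ((0.0, 0.0), 0.0)
        cfg = MCMCConfig(2, 200, 100, 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = HierarchicalDDM(model="DDM", priors=priors, config=cfg,
                                  random_state=3).fit(oriented_small)
        assert np.all(est.result_.draws["change"] == 0.0)
        # deviance equals a direct pooled evaluation at the same draws
        b = est.result_.draws["baseline"][0, -1]
        ll = (est._cond_loglik(b, "sated").sum()
              + est._cond_loglik(b, "hungry").sum())
        assert est.result_.deviance[0, -1] == pytest.approx(-2 * ll)

    def test_get_set_params(self):
        est = HierarchicalDDM(model="DDM")
        est.set_params(random_state=9)
        assert est.get_params()["random_state"] == 9
        with pytest.raises(ValueError):
            est.set_params(bogus=1)
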