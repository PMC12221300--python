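"""Model registry, transforms, value scaling and drift-equation algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazeddm.models import (MODEL_NAMES, ModelSpec, constrain_params, inv_softplus,
                            model_registry, probit, scale_values, softplus,
                            value_difference)


class TestRegistry:
    def test_eight_variants(self):
        assert len(MODEL_NAMES) == 8

    @pytest.mark.parametrize("name,estimated,beta_fixed", [
        ("DDM", {"alpha", "ndt", "d", "omega"}, True),
        ("DDMsp", {"alpha", "ndt", "d", "omega", "beta"}, False),
        ("aDDM", {"alpha", "ndt", "d", "omega", "theta"}, True),
        ("aDDMsp", {"alpha", "ndt", "d", "omega", "beta", "theta"}, False),
        ("maaDDM", {"alpha", "ndt", "d", "omega", "theta", "phi"}, True),
        ("maaDDMsp", {"alpha", "ndt", "d", "omega", "beta", "theta", "phi"}, False),
        ("maaDDM2phi", {"alpha", "ndt", "d", "omega", "theta", "phi_t", "phi_h"}, True),
        ("maaDDM2phi_sp",
         {"alpha", "ndt", "d", "omega", "beta", "theta", "phi_t", "phi_h"}, False),
    ])
    def test_parameter_flags(self, name, estimated, beta_fixed):
        spec = model_registry(name)
        assert set(spec.estimated) == estimated
        if beta_fixed:
            assert spec.fixed["beta"] == 0.5

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError, match="maaDDM2phi"):
            model_registry("mtDDM")

    def test_invalid_spec_combinations(self):
        # second attribute discount requires the first; discounts require theta
        with pytest.raises(ValueError):
            ModelSpec("bad", ("alpha", "ndt", "d", "omega", "theta", "phi_h"))
        with pytest.raises(ValueError):
            ModelSpec("bad", ("alpha", "ndt", "d", "omega", "phi"))

    def test_param_spec_mismatch_rejected(self):
        spec = model_registry("maaDDM")
        with pytest.raises(ValueError, match="common phi"):
            spec.validate_params({"alpha": 1, "phi_t": 0.5})

    def test_json_round_trip(self):
        spec = model_registry("maaDDM2phi")
        assert ModelSpec.from_json(spec.to_json()) == spec


class TestTransforms:
    def test_softplus_closed_forms(self):
        assert softplus(0.0) == pytest.approx(np.log(2), abs=1e-12)
        assert softplus(2.0) == pytest.approx(2.1269280110429727, abs=1e-10)

    def test_probit_center(self):
        assert probit(0.0) == pytest.approx(0.5, abs=1e-12)

    def test_inv_softplus_round_trip(self):
        x = np.linspace(-3, 5, 50)
        np.testing.assert_allclose(inv_softplus(softplus(x)), x, atol=1e-9)

    def test_constrain_applies_transforms_and_fixed_values(self):
        spec = model_registry("maaDDM2phi")
        p = constrain_params(spec, {"alpha": 0.0, "ndt": -1.0, "d": 0.06,
                                    "omega": 0.0, "theta": 0.7, "phi_t": 0.9,
                                    "phi_h": 0.4})
        assert p.alpha == pytest.approx(np.log(2))
        assert p.omega == pytest.approx(0.5)
        assert p.beta == 0.5          # fixed, untouched by transform
        assert p.theta == 0.7         # identity


class TestScaleValues:
    def test_affine_map_endpoints(self):
        df = pd.DataFrame({"participant": 1, "taste": [0.0, 50.0, 100.0]})
        out = scale_values(df, ["taste"])
        np.testing.assert_allclose(out["taste"], [1.0, 5.5, 10.0])

    def test_constant_input_maps_to_midpoint(self):
        df = pd.DataFrame({"participant": 1, "taste": [42.0] * 5})
        out = scale_values(df, ["taste"])
        assert (out["taste"] == 5.5).all()

    def test_nonfinite_rows_rejected_and_reported(self):
        df = pd.DataFrame({"participant": [1, 1, 1], "taste": [1.0, np.nan, 3.0]})
        out = scale_values(df, ["taste"])
        assert len(out) == 2
        assert out.attrs["rejected_rows"] == [1]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 10000), min_size=3, max_size=20, unique=True))
    def test_order_preserved_and_range(self, raw_ticks):
        raw = [x / 100.0 for x in raw_ticks]  # slider with 0.01 resolution
        df = pd.DataFrame({"participant": 1, "taste": raw})
        out = scale_values(df, ["taste"])
        scaled = out["taste"].to_numpy()
        assert np.all(scaled >= 1.0 - 1e-12) and np.all(scaled <= 10.0 + 1e-12)
        order = np.argsort(raw)
        assert np.all(np.diff(scaled[order]) > 0)


def _random_trial(rng):
    values = tuple(rng.uniform(1, 10, size=4))
    shares = rng.dirichlet(np.ones(4))
    return values, tuple(shares)


class TestValueDifference:
    def test_identical_options_give_zero_under_balanced_gaze(self, rng):
        # with unequal gaze an attentional discount biases toward the fixated
        # option even at equal values (the models' signature effect), so the
        # symmetry statement needs balanced dwell
        shares = (0.25, 0.25, 0.25, 0.25)
        for name in MODEL_NAMES:
            spec = model_registry(name)
            raw = {p: rng.normal() for p in spec.estimated}
            params = constrain_params(spec, raw)
            vd = value_difference(spec, params, (6.0, 6.0, 3.0, 3.0), shares)
            assert vd == pytest.approx(0.0, abs=1e-12)

    def test_identical_options_gaze_free_model_any_gaze(self, rng):
        spec = model_registry("DDM")
        params = constrain_params(spec, {p: rng.normal() for p in spec.estimated})
        _, shares = _random_trial(rng)
        vd = value_difference(spec, params, (6.0, 6.0, 3.0, 3.0), shares)
        assert vd == pytest.approx(0.0, abs=1e-12)

    def test_hand_expanded_two_discount_equation(self):
        # omega=0.7, theta=0.5, phi_t=0.9, phi_h=0.6, T=(8,2), H=(2,8),
        # shares (0.4, 0.1, 0.4, 0.1); expanded term by term on paper:
        # 0.4*(0.7*7 + 0.3*0.6*(-2)) + 0.1*(0.7*0.9*7 + 0.3*(-2))
        # + 0.4*(0.7*2 + 0.3*0.6*(-7)) + 0.1*(0.7*0.9*2 + 0.3*(-7)) = 2.169
        spec = model_registry("maaDDM2phi")
        params = constrain_params(spec, {
            "alpha": 1.0, "ndt": -1.0, "d": 0.1, "omega": 0.0,
            "theta": 0.5, "phi_t": 0.9, "phi_h": 0.6}).replace(omega=0.7)
        vd = value_difference(spec, params, (8.0, 2.0, 2.0, 8.0),
                              (0.4, 0.1, 0.4, 0.1))
        assert vd == pytest.approx(2.169, abs=1e-12)

    def test_nesting_identities_machine_precision(self, rng):
        """Equal attribute discounts collapse to the common-discount model,
        discount one to the option-level model, and theta=1 to the plain
        weighted difference — exactly, for arbitrary gaze."""
        for _ in range(200):
            values, shares = _random_trial(rng)
            omega, theta, phi = rng.uniform(0.05, 0.95), rng.uniform(0, 1.5), rng.uniform(0, 1.5)
            base = dict(alpha=1.0, ndt=-1.0, d=0.1)
            p4 = constrain_params(model_registry("maaDDM2phi"),
                                  {**base, "omega": 0.0, "theta": theta,
                                   "phi_t": phi, "phi_h": phi}).replace(omega=omega)
            p3 = constrain_params(model_registry("maaDDM"),
                                  {**base, "omega": 0.0, "theta": theta,
                                   "phi": phi}).replace(omega=omega)
            assert value_difference(None, p4, values, shares) == pytest.approx(
                value_difference(None, p3, values, shares), abs=1e-13)
            p3_unit = p3.replace(phi_t=1.0, phi_h=1.0)
            p2 = constrain_params(model_registry("aDDM"),
                                  {**base, "omega": 0.0, "theta": theta}).replace(omega=omega)
            assert value_difference(None, p3_unit, values, shares) == pytest.approx(
                value_difference(None, p2, values, shares), abs=1e-13)
            p1 = constrain_params(model_registry("DDM"),
                                  {**base, "omega": 0.0}).replace(omega=omega)
            t_i, t_j, h_i, h_j = values
            expected = omega * (t_i - t_j) + (1 - omega) * (h_i - h_j)
            assert value_difference(None, p1, values, shares) == pytest.approx(
                expected, abs=1e-13)

    def test_option_swap_antisymmetry(self, rng):
        for name in MODEL_NAMES:
            spec = model_registry(name)
            raw = {p: rng.normal(0, 0.5) for p in spec.estimated}
            params = constrain_params(spec, raw)
            (t_i, t_j, h_i, h_j), (f_it, f_ih, f_jt, f_jh) = _random_trial(rng)
            vd = value_difference(spec, params, (t_i, t_j, h_i, h_j),
                                  (f_it, f_ih, f_jt, f_jh))
            vd_swapped = value_difference(spec, params, (t_j, t_i, h_j, h_i),
                                          (f_jt, f_jh, f_it, f_ih))
            assert vd_swapped == pytest.approx(-vd, abs=1e-12)

    @pytest.mark.parametrize("omega,dead_attr", [(1.0, "health"), (0.0, "taste")])
    def test_extreme_weight_kills_other_attribute(self, rng, omega, dead_attr):
        spec = model_registry("maaDDM2phi")
        params = constrain_params(spec, {"alpha": 1.0, "ndt": -1.0, "d": 0.1,
                                         "omega": 0.0, "theta": 0.6,
                                         "phi_t": 0.8, "phi_h": 0.5}).replace(omega=omega)
        values, shares = _random_trial(rng)
        vd0 = value_difference(spec, params, values, shares)
        t_i, t_j, h_i, h_j = values
        if dead_attr == "health":
            perturbed = (t_i, t_j, h_i + 3, h_j - 2)
        else:
            perturbed = (t_i + 3, t_j - 2, h_i, h_j)
        vd1 = value_difference(spec, params, perturbed, shares)
        assert vd1 == pytest.approx(vd0, abs=1e-12)
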