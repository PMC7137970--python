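"""Pointwise feedback and rate functions: values, invariants, monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemage import (
    FeedbackConfig,
    ModelParams,
    SegregationRule,
    cycle_speed,
    division_fractions,
    hill_signal,
    sigmoid_f,
    sigmoid_g,
)
from stemage.model_core import ConfigurationError


class TestHillSignal:
    @pytest.mark.parametrize(
        "P,k,m,expected",
        [
            (0.0, 1e-8, 2, 1.0),  # maximal signal in the absence of cells
            (1e8, 1e-8, 2, 0.5),  # kP = 1 halves the signal
            (2e8, 1e-8, 2, 0.2),  # 1/(1+2^2)
        ],
    )
    def test_values(self, P, k, m, expected):
        assert hill_signal(P, k, m) == pytest.approx(expected, rel=1e-12)

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError):
            hill_signal(-1.0, 1e-8, 2)

    def test_strictly_decreasing(self):
        P = np.linspace(0, 1e9, 50)
        s = hill_signal(P, 1e-8, 2)
        assert np.all(np.diff(s) < 0)


class TestSigmoids:
    def test_midpoint_and_limits(self, fb_td_stem):
        # midpoint: a1 + b1/2 = 1.1 - 0.35
        assert sigmoid_f(0.75, fb_td_stem) == pytest.approx(0.75, rel=1e-12)
        assert sigmoid_f(0.0, fb_td_stem) == pytest.approx(1.0999997, abs=1e-6)
        assert sigmoid_f(100.0, fb_td_stem) == pytest.approx(0.4, rel=1e-9)
        assert sigmoid_g(0.75, fb_td_stem) == pytest.approx(0.75, rel=1e-12)

    def test_strictly_decreasing(self, fb_td_stem):
        a = np.linspace(0, 1, 101)
        assert np.all(np.diff(sigmoid_f(a, fb_td_stem)) < 0)
        assert np.all(np.diff(sigmoid_g(a, fb_td_stem)) < 0)


class TestDivisionFractions:
    def test_basal_without_feedback(self, base_params, fb_none):
        assert division_fractions(0, 0, 0.2, base_params, fb_none) == pytest.approx(
            (0.6, 0.3, 0.1)
        )

    def test_td_only_at_zero_population_is_basal(self, base_params, fb_td):
        assert division_fractions(0, 0, 0.0, base_params, fb_td) == pytest.approx(
            (0.6, 0.3, 0.1)
        )

    def test_td_only_hand_value(self, base_params, fb_td):
        # k1T PT = 1 halves delta1; k2T PT = 0.5 gives delta2 = 0.3/1.25
        d1, d2, d3 = division_fractions(1e8, 0, 0.0, base_params, fb_td)
        assert d1 == pytest.approx(0.3, rel=1e-12)
        assert d2 == pytest.approx(0.24, rel=1e-12)
        assert d3 == pytest.approx(0.46, rel=1e-12)

    def test_td_stem_sigmoid_midpoint(self, base_params, fb_td_stem):
        d1, _, _ = division_fractions(0, 0, 0.75, base_params, fb_td_stem)
        assert d1 == pytest.approx(0.6 * 0.75, rel=1e-12)

    def test_step_limit_at_large_hill_exponent(self, base_params):
        fb = FeedbackConfig(mode="td_only", mT=50)
        below = division_fractions(0.9 / fb.k1T, 0, 0.0, base_params, fb)[0]
        above = division_fractions(1.1 / fb.k1T, 0, 0.0, base_params, fb)[0]
        assert below == pytest.approx(0.6, rel=1e-2)
        assert above == pytest.approx(0.0, abs=1e-2)

    @settings(max_examples=200, deadline=None)
    @given(
        PT=st.floats(0, 1e10),
        PS=st.floats(0, 1e10),
        a=st.floats(0, 1.0),
        mode=st.sampled_from(["none", "td_only", "td_stem"]),
    )
    def test_probability_triple(self, PT, PS, a, mode):
        params = ModelParams()
        fb = FeedbackConfig(mode=mode)
        d = division_fractions(PT, PS, a, params, fb)
        assert all(0.0 <= x <= 1.0 for x in d)
        assert sum(d) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("mode", ["td_only", "td_stem"])
    def test_monotone_nonincreasing_in_populations(self, base_params, mode, rng):
        fb = FeedbackConfig(mode=mode)
        pops = np.sort(rng.uniform(0, 5e8, 30))
        for a in (0.1, 0.5, 0.9):
            d1 = [division_fractions(P, 0, a, base_params, fb)[0] for P in pops]
            d1s = [division_fractions(0, P, a, base_params, fb)[0] for P in pops]
            v = [cycle_speed(P, 0, a, base_params, fb) for P in pops]
            assert np.all(np.diff(d1) <= 1e-15)
            assert np.all(np.diff(d1s) <= 1e-15)
            assert np.all(np.diff(v) <= 1e-15)


class TestCycleSpeed:
    def test_values(self, base_params, fb_none, fb_td, fb_td_stem):
        assert cycle_speed(0, 0, 0.0, base_params, fb_none) == pytest.approx(0.2)
        # kvT PT = 1 halves the speed
        assert cycle_speed(2e8, 0, 0.0, base_params, fb_td) == pytest.approx(0.1)
        # sigmoid midpoint: 0.2 * 0.75
        assert cycle_speed(0, 0, 0.75, base_params, fb_td_stem) == pytest.approx(0.15)


class TestValidation:
    def test_delta0_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            ModelParams(delta0=(0.5, 0.4, 0.2))

    def test_alpha1_convention(self):
        with pytest.raises(ConfigurationError):
            SegregationRule(alpha1=0.6)

    def test_positive_rates(self):
        with pytest.raises(ConfigurationError):
            ModelParams(v_p=0.0)

    def test_unknown_mode(self):
        with pytest.raises(ConfigurationError):
            FeedbackConfig(mode="everything")

    def test_derived_fractions_complementary(self):
        r = SegregationRule(alpha1=0.3, beta1=0.2, gamma1=0.1)
        assert r.alpha1 + r.alpha2 == 1.0
        assert r.beta1 + r.beta2 == 1.0
        assert r.gamma1 + r.gamma2 == 1.0
        assert r.omega1 == 0.1 and r.omega2 == 0.7
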