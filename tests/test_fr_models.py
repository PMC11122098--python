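"""Functional-response prediction curves: closed forms, implicit solver,
reductions between families, and qualitative invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frfit import (
    FRModelSpec,
    FRParameters,
    max_feeding_rate,
    predict_flexq,
    predict_hassell3,
    predict_holling2,
    predict_rogers2,
)


class TestHolling2:
    @pytest.mark.parametrize(
        "a,h,n,t,expected",
        [
            (1.0, 0.1, 10, 1.0, 5.0),       # 10/(1+1) by hand
            (0.0, 0.1, 50, 1.0, 0.0),       # no attacks
            (2.0, 0.0, 3, 1.0, 6.0),        # linear when handling is free
        ],
    )
    def test_closed_form(self, a, h, n, t, expected):
        assert predict_holling2(a, h, n, t) == pytest.approx(expected)

    def test_saturates_at_t_over_h(self):
        assert predict_holling2(2.0, 0.5, 1e12, 1.0) == pytest.approx(2.0, rel=1e-6)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            predict_holling2(-1.0, 0.1, 10, 1.0)
        with pytest.raises(ValueError):
            predict_holling2(1.0, 0.1, 10, 0.0)


class TestRogers2:
    def test_zero_attack_rate_eats_nothing(self):
        assert predict_rogers2(0.0, 0.05, 50, 1.0) == 0.0

    def test_zero_handling_time_closed_form(self):
        # h = 0: pure exponential depletion, Ne = N0 (1 - e^{-aT})
        assert predict_rogers2(1.0, 0.0, 10, 1.0) == pytest.approx(
            10 * (1 - np.exp(-1)), abs=1e-12
        )

    def test_agrees_with_fixed_point_oracle(self, rogers_oracle, noap2_params):
        got = predict_rogers2(noap2_params.a, noap2_params.h, 80, 1.0)
        assert got == pytest.approx(
            rogers_oracle(noap2_params.a, noap2_params.h, 80, 1.0), abs=1e-8
        )

    def test_implicit_residual_small_on_random_grid(self, rogers_oracle):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.uniform(0.01, 3.0)
            h = rng.uniform(0.001, 0.5)
            n0 = int(rng.integers(1, 201))
            t = float(rng.choice([0.5, 1.0, 2.0]))
            ne = predict_rogers2(a, h, n0, t)
            residual = ne - n0 * (1 - np.exp(a * (h * ne - t)))
            assert abs(residual) < 1e-10
            assert ne == pytest.approx(rogers_oracle(a, h, n0, t), abs=1e-8)
            assert 0.0 <= ne <= n0

    def test_overflow_regime_stays_physical(self):
        # a h N0 far beyond exp() overflow: solution pinned just under T/h
        ne = predict_rogers2(10.0, 0.5, 500, 1.0)
        assert 0.0 < ne <= 2.0
        residual = ne - 500 * (1 - np.exp(10.0 * (0.5 * ne - 1.0)))
        assert abs(residual) < 1e-10

    def test_vectorized_matches_scalar(self):
        n0 = np.array([5.0, 10.0, 25.0, 50.0, 80.0])
        vec = predict_rogers2(0.9797, 0.0104, n0, 1.0)
        assert vec == pytest.approx(
            [predict_rogers2(0.9797, 0.0104, x, 1.0) for x in n0], abs=0
        )


class TestFlexq:
    def test_q_zero_is_rogers_bit_for_bit(self):
        n0 = np.array([1.0, 5.0, 10.0, 25.0, 50.0, 80.0, 200.0])
        flex = predict_flexq(0.5, 0.0, 0.02, n0, 1.0)
        rog = predict_rogers2(0.5, 0.02, n0, 1.0)
        assert np.array_equal(flex, rog)
        assert predict_flexq(0.5, 0.0, 0.02, 25, 1.0) == predict_rogers2(
            0.5, 0.02, 25, 1.0
        )

    def test_agrees_with_oracle_at_generalized_fit_values(self, rogers_oracle):
        # effective attack rate a = b N0^q inside the depletion equation
        b, q, h = 0.0028, 2.1645, 0.0228
        got = predict_flexq(b, q, h, 80, 1.0)
        assert got == pytest.approx(rogers_oracle(b * 80**q, h, 80, 1.0), abs=1e-8)

    def test_zero_density_with_negative_q(self):
        assert predict_flexq(0.5, -1.0, 0.02, 0, 1.0) == 0.0

    def test_positive_q_raises_proportion_at_low_density(self):
        # type-III signature: proportion consumed increases with N0 low down
        p1 = predict_flexq(0.02, 1.0, 0.01, 2, 1.0) / 2
        p2 = predict_flexq(0.02, 1.0, 0.01, 10, 1.0) / 10
        assert p2 > p1


class TestHassell3:
    def test_reduces_to_rogers_when_only_baseline_attack(self):
        n0 = np.array([5.0, 25.0, 80.0])
        assert np.array_equal(
            predict_hassell3(0.0, 0.0, 1.0, 0.02, n0, 1.0),
            predict_rogers2(1.0, 0.02, n0, 1.0),
        )

    def test_matches_flexq_q1_when_unsaturated(self):
        # c = d = 0 leaves a_eff = b N0, the flexible family at q = 1
        assert predict_hassell3(0.03, 0.0, 0.0, 0.02, 50, 1.0) == pytest.approx(
            predict_flexq(0.03, 1.0, 0.02, 50, 1.0), abs=1e-12
        )

    def test_agrees_with_oracle(self, rogers_oracle):
        b, c, d, h, n0 = 0.3, 0.05, 0.1, 0.02, 50
        a_eff = (d + b * n0) / (1 + c * n0)
        assert predict_hassell3(b, c, d, h, n0, 1.0) == pytest.approx(
            rogers_oracle(a_eff, h, n0, 1.0), abs=1e-8
        )


class TestMaxFeedingRate:
    @pytest.mark.parametrize(
        "h,expected_rounded",
        [(0.0228, 44), (0.0104, 96), (1.0, 1)],
    )
    def test_reciprocal_of_handling_time(self, h, expected_rounded):
        assert round(max_feeding_rate(h, 1.0)) == expected_rounded

    def test_zero_handling_time_is_an_error(self):
        with pytest.raises(ValueError):
            max_feeding_rate(0.0, 1.0)


class TestModelSpec:
    def test_requires_active_parameters(self):
        with pytest.raises(ValueError):
            FRModelSpec("rogers2", FRParameters(a=1.0))  # h missing
        with pytest.raises(ValueError):
            FRModelSpec("nonsense", FRParameters(a=1.0, h=0.1))

    def test_dispatches_to_family(self):
        spec = FRModelSpec("rogers2", FRParameters(a=1.0, h=0.02, T=1.0))
        assert spec.predict(50) == predict_rogers2(1.0, 0.02, 50, 1.0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    a=st.floats(0.01, 3.0),
    h=st.floats(0.0, 0.5),
    n0=st.integers(0, 200),
    t=st.sampled_from([0.5, 1.0, 2.0]),
)
def test_rogers_bounds_and_monotonicity(a, h, n0, t):
    """0 <= Ne <= N0; Ne non-decreasing in N0, a and T."""
    ne = predict_rogers2(a, h, n0, t)
    assert 0.0 <= ne <= n0
    assert predict_rogers2(a, h, n0 + 5, t) >= ne - 1e-9
    assert predict_rogers2(a * 1.5, h, n0, t) >= ne - 1e-9
    assert predict_rogers2(a, h, n0, t * 1.5) >= ne - 1e-9


@settings(deadline=None, max_examples=40, derandomize=True)
@given(h=st.floats(0.005, 0.5), a=st.floats(0.05, 3.0))
def test_rogers_saturation_approaches_t_over_h(a, h):
    t = 1.0
    assert predict_rogers2(a, h, 10_000_000, t) <= t / h + 1e-6
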