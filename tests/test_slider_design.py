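"""Closed-form properties of the quadratic slider design."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lambdaslider.slider_design import (
    QuadraticSliderSpec,
    equal_payoff_point,
    equal_payoff_roots,
    payoff_at,
    payoff_ranges,
    position_from_raw,
    raw_from_position,
    slider_from_json,
    slider_to_json,
    validate,
)


def spec(a=11.25, bs=70.0, bt=50.0, xmin=-2.0, xmax=2.0, **kw):
    return QuadraticSliderSpec(a=a, bs=bs, bt=bt, xmin=xmin, xmax=xmax, **kw)


valid_specs = st.builds(
    spec,
    a=st.floats(0.1, 20),
    bs=st.floats(-50, 50),
    bt=st.floats(-50, 50),
    xmin=st.floats(-3, -0.1),
    xmax=st.floats(0.1, 3),
)


class TestPayoffs:
    @pytest.mark.parametrize(
        "s, x, expected",
        [
            (spec(), 0.0, (70.0, 50.0)),
            (spec(), 2.0, (25.0, 95.0)),  # endpoint of the published design
            (spec(a=1, bs=0, bt=0), -1.0, (-1.0, -2.0)),
        ],
    )
    def test_payoff_at(self, s, x, expected):
        p = payoff_at(s, x)
        assert (p.ws, p.wt) == pytest.approx(expected)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            payoff_at(spec(), 2.5)

    def test_ranges_of_reference_design(self, standard):
        (ws_lo, ws_hi), (wt_lo, wt_hi) = payoff_ranges(standard)
        assert (ws_lo, ws_hi) == (25.0, 70.0)
        assert (wt_lo, wt_hi) == (5.0, 95.0)

    def test_ranges_monotone_case(self):
        (ws_lo, ws_hi), (wt_lo, wt_hi) = payoff_ranges(spec(a=1, bs=1, bt=0, xmin=0, xmax=1))
        assert (ws_lo, ws_hi) == (0.0, 1.0)
        assert (wt_lo, wt_hi) == (0.0, 2.0)

    def test_ranges_match_dense_grid(self, rng):
        for _ in range(50):
            s = spec(
                a=rng.uniform(0.5, 15),
                bs=rng.uniform(-20, 80),
                bt=rng.uniform(-20, 80),
                xmin=rng.uniform(-3, 0.5),
                xmax=rng.uniform(0.6, 3),
            )
            g = np.linspace(s.xmin, s.xmax, 10_001)
            ws = -s.a * g * g + s.bs
            wt = 2 * s.a * g + s.bt
            (ws_lo, ws_hi), (wt_lo, wt_hi) = payoff_ranges(s)
            # the grid may miss the parabola vertex by up to a*(h/2)^2
            h = (s.xmax - s.xmin) / 10_000
            tol = s.a * h * h + 1e-9
            assert ws_lo == pytest.approx(ws.min(), abs=tol)
            assert ws_hi == pytest.approx(ws.max(), abs=tol)
            assert wt_lo == pytest.approx(wt.min(), abs=1e-9)
            assert wt_hi == pytest.approx(wt.max(), abs=1e-9)


class TestRawMapping:
    @pytest.mark.parametrize(
        "xmin, xmax, chi, expected",
        [(-2, 2, 0.75, 1.0), (-1, 1, 0.75, 0.5), (-2.75, 1.25, 0.0, -2.75)],
    )
    def test_examples(self, xmin, xmax, chi, expected):
        s = spec(xmin=xmin, xmax=xmax)
        assert position_from_raw(s, chi) == pytest.approx(expected)

    @given(valid_specs, st.floats(0, 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_mutual_inverse(self, s, chi):
        assert raw_from_position(s, position_from_raw(s, chi)) == pytest.approx(chi, abs=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            position_from_raw(spec(), 1.5)


class TestEqualPayoffPoint:
    def test_reference_design(self, standard):
        assert equal_payoff_point(standard) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_two_roots_in_range(self):
        # -x^2 = 2x has roots 0 and -2, both on the range boundary;
        # the larger is returned, both are reported
        s = spec(a=1, bs=0, bt=0, xmin=-2, xmax=0)
        assert equal_payoff_roots(s) == pytest.approx((-2.0, 0.0))
        assert equal_payoff_point(s) == pytest.approx(0.0)

    def test_absent_when_one_party_always_ahead(self, sliders):
        assert equal_payoff_point(sliders["self_more"]) is None
        assert equal_payoff_point(sliders["target_more"]) is None

    def test_root_solves_equation(self, sliders):
        for s in sliders.values():
            x = equal_payoff_point(s)
            if x is not None:
                p = payoff_at(s, x)
                assert p.ws == pytest.approx(p.wt, abs=1e-9)


class TestValidation:
    def test_reference_design_valid(self, standard):
        assert validate(standard) == []

    def test_negative_scale(self):
        out = validate(spec(a=-1))
        assert any("a must be positive" in v for v in out)

    def test_display_bound_violation(self):
        # widening the reference range to [-3, 3] drives wt down to -17.5
        out = validate(spec(xmin=-3, xmax=3))
        assert any("target payoff" in v for v in out)


class TestConcavity:
    def test_self_payoff_concave_in_target_payoff(self, rng):
        """Along any valid slider, ws = f(wt) is strictly concave (the
        geometry that makes every position dominant for some lambda)."""
        for _ in range(30):
            s = spec(
                a=rng.uniform(0.5, 15),
                bs=rng.uniform(-20, 80),
                bt=rng.uniform(-20, 80),
                xmin=rng.uniform(-3, -0.5),
                xmax=rng.uniform(0.5, 3),
            )
            xs = np.sort(rng.uniform(s.xmin, s.xmax, 10))
            ws = -s.a * xs**2 + s.bs
            wt = 2 * s.a * xs + s.bt  # increasing in x
            slopes = np.diff(ws) / np.diff(wt)
            assert np.all(np.diff(slopes) < 0)


class TestSerialization:
    def test_json_roundtrip(self, standard):
        assert slider_from_json(slider_to_json(standard)) == standard

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError):
            slider_from_json({"a": 1, "bs": 0, "bt": 0, "xmin": -1, "xmax": 1, "curvature": 2})

    def test_fixture_suite_is_valid(self, sliders):
        assert len(sliders) >= 6
        for s in sliders.values():
            assert validate(s) == []

    def test_offset_fixtures_keep_payoff_order(self, sliders):
        """The self-more fixture keeps ws > wt and the target-more fixture
        ws < wt over the whole range (required for joint kappa estimation)."""
        g = np.linspace(-2, 2, 2001)
        for name, sign in [("self_more", 1), ("target_more", -1)]:
            s = sliders[name]
            diff = (-s.a * g**2 + s.bs) - (2 * s.a * g + s.bt)
            assert np.all(sign * diff > 0)
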