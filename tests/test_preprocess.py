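"""Curve preprocessing: interpolation, normalization, upslope detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aopwv import (
    TemplateWaveform,
    VelocityCurve,
    decile_segment,
    detect_systolic_upslope,
    interpolate_1ms,
    make_template,
    normalize,
    preprocess,
)


def linear_ramp_curve():
    """Normalized curve rising 0 -> 1 over [0, 100] ms, then flat decay."""
    t = np.arange(0.0, 400.0, 1.0)
    v = np.clip(t / 100.0, 0.0, 1.0)
    v[t > 200] = np.maximum(1.0 - (t[t > 200] - 200) / 150.0, 0.0)
    return VelocityCurve(times=t, velocities=v)


class TestVelocityCurve:
    def test_rejects_non_uniform_grid(self):
        with pytest.raises(ValueError, match="uniform"):
            VelocityCurve(times=[0.0, 1.0, 3.0, 4.0], velocities=[0.0] * 4)

    def test_rejects_decreasing_times(self):
        with pytest.raises(ValueError, match="increasing"):
            VelocityCurve(times=[0.0, 2.0, 1.0, 3.0], velocities=[0.0] * 4)


class TestInterpolate1ms:
    def test_linear_data_reproduced_exactly(self):
        t = np.arange(0.0, 400.0, 20.0)
        c = interpolate_1ms(VelocityCurve(times=t, velocities=0.3 * t))
        assert c.dt == 1.0
        np.testing.assert_allclose(c.velocities, 0.3 * c.times, atol=1e-10)

    def test_cubic_polynomial_reproduced(self):
        t = np.arange(0.0, 200.0, 10.0)
        poly = lambda x: 1e-5 * x**3 - 2e-3 * x**2 + 0.1 * x + 3.0
        c = interpolate_1ms(VelocityCurve(times=t, velocities=poly(t)))
        np.testing.assert_allclose(c.velocities, poly(c.times), atol=1e-8)

    def test_passes_through_knots(self, template):
        t = np.arange(50) * 20.0
        rng = np.random.default_rng(7)
        v = rng.normal(size=50)
        c = interpolate_1ms(VelocityCurve(times=t, velocities=v))
        np.testing.assert_allclose(c.velocities[::20], v, atol=1e-12)

    def test_50_frame_sampling_recovers_dense_template(self, template):
        dense = make_template(template)
        t50 = np.arange(50) * 20.0
        sampled = VelocityCurve(
            times=t50, velocities=np.interp(t50, dense.times, dense.velocities)
        )
        interp = interpolate_1ms(sampled)
        n = interp.n_samples
        rms = np.sqrt(np.mean((interp.velocities - dense.velocities[:n]) ** 2))
        assert rms < 0.01 * template.peak_velocity

    def test_rejects_non_uniform_input(self):
        with pytest.raises(ValueError):
            interpolate_1ms(VelocityCurve(times=[0, 10, 21, 30], velocities=[0, 1, 2, 3]))


class TestNormalize:
    def test_maps_to_unit_interval(self):
        t = np.arange(0.0, 100.0, 10.0)
        c = normalize(VelocityCurve(times=t, velocities=np.linspace(-5, 80, 10)))
        assert c.velocities.min() == 0.0
        assert c.velocities.max() == 1.0

    def test_idempotent(self):
        t = np.arange(0.0, 100.0, 10.0)
        c = normalize(VelocityCurve(times=t, velocities=np.linspace(0, 80, 10)))
        np.testing.assert_array_equal(normalize(c).velocities, c.velocities)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), offset=st.floats(-100.0, 100.0))
    def test_affine_invariance(self, scale, offset):
        t = np.arange(0.0, 100.0, 10.0)
        v = np.array([0.0, 2, 5, 9, 8, 6, 4, 3, 2, 1])
        a = normalize(VelocityCurve(times=t, velocities=v))
        b = normalize(VelocityCurve(times=t, velocities=scale * v + offset))
        np.testing.assert_allclose(a.velocities, b.velocities, atol=1e-9)

    def test_constant_curve_rejected(self):
        t = np.arange(0.0, 100.0, 10.0)
        with pytest.raises(ValueError, match="constant"):
            normalize(VelocityCurve(times=t, velocities=np.full(10, 3.0)))


class TestDetectSystolicUpslope:
    def test_half_cosine_deciles_match_closed_form(self, template):
        """Crossing of level L on a half-cosine rise: t = foot + (rise/pi) acos(1-2L)."""
        curve = preprocess(make_template(template))
        w = detect_systolic_upslope(curve)
        rise, foot = template.t_rise, template.foot_time
        t_02 = foot + rise / math.pi * math.acos(1 - 2 * 0.2)
        t_08 = foot + rise / math.pi * math.acos(1 - 2 * 0.8)
        assert w.decile_lo_time == pytest.approx(t_02, abs=1.0)
        assert w.decile_hi_time == pytest.approx(t_08, abs=1.0)
        assert w.peak_time == pytest.approx(foot + rise, abs=1.0)

    def test_linear_ramp_decile_window(self):
        w = detect_systolic_upslope(linear_ramp_curve())
        assert w.decile_lo_time == pytest.approx(20.0, abs=0.5)
        assert w.decile_hi_time == pytest.approx(80.0, abs=0.5)

    @pytest.mark.parametrize("delta", [10.0, 30.0, 55.0])
    def test_shift_equivariance(self, template, delta):
        """Shifting the input shifts every landmark by the same amount."""
        from aopwv.synthetic import template_value

        t = np.arange(0.0, 1000.0, 1.0)
        a = preprocess(VelocityCurve(times=t, velocities=template_value(template, t)))
        b = preprocess(
            VelocityCurve(times=t, velocities=template_value(template, t - delta))
        )
        wa, wb = detect_systolic_upslope(a), detect_systolic_upslope(b)
        for field_name in ("foot_time", "peak_time", "decile_lo_time", "decile_hi_time"):
            assert getattr(wb, field_name) - getattr(wa, field_name) == pytest.approx(
                delta, abs=0.5
            )

    def test_requires_normalized_input(self, template):
        with pytest.raises(ValueError, match="normalized"):
            detect_systolic_upslope(make_template(template))

    def test_non_monotone_upslope_warns(self):
        t = np.arange(0.0, 300.0, 1.0)
        v = np.clip(t / 100.0, 0, 1.0)
        v[40:45] = v[40] - 0.02  # small dip on the upslope
        v[t > 150] = 0.0
        with pytest.warns(UserWarning, match="non-monotone"):
            detect_systolic_upslope(VelocityCurve(times=t, velocities=v))


class TestDecileSegment:
    def test_linear_ramp_segment_has_61_samples(self):
        c = linear_ramp_curve()
        seg = decile_segment(c, detect_systolic_upslope(c))
        assert seg.n_samples == 61
        assert seg.times[0] == 20.0 and seg.times[-1] == 80.0

    def test_values_within_decile_band(self, template):
        c = preprocess(make_template(template))
        seg = decile_segment(c, detect_systolic_upslope(c))
        step = np.max(np.abs(np.diff(c.velocities)))
        assert seg.velocities.min() >= 0.2 - step
        assert seg.velocities.max() <= 0.8 + step

    def test_empty_segment_rejected(self):
        c = linear_ramp_curve()
        w = detect_systolic_upslope(c)
        bad = type(w)(
            foot_time=w.foot_time,
            peak_time=w.peak_time,
            decile_lo_time=30.2,
            decile_hi_time=30.8,
        )
        t = np.arange(0.0, 400.0, 50.0)
        coarse = VelocityCurve(times=t, velocities=np.linspace(0, 1, t.size))
        with pytest.raises(ValueError, match="empty"):
            decile_segment(coarse, bad)
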