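"""Waveform preprocessing shared by every PWV strategy.

Acquisition-resolution mean-velocity curves are brought to a common analysis
representation: cubic-spline interpolation to a 1-ms time grid, min-max
normalization to [0, 1], detection of the systolic upslope (foot, peak) and
of the 2nd/8th-decile amplitude crossings that delimit the portion of the
upslope least contaminated by reflected waves.

Internal unit system: time in ms, distance in mm, velocity in cm/s and pulse
wave velocity in m/s (1 m/s = 1 mm/ms at the boundaries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "VelocityCurve",
    "UpslopeWindow",
    "interpolate_1ms",
    "normalize",
    "detect_systolic_upslope",
    "decile_segment",
    "preprocess",
]

#: amplitude level (normalized units) below which the curve is considered
#: pre-systolic baseline; the foot is the last sub-threshold sample before
#: the peak
FOOT_THRESHOLD = 0.05

#: amplitude fractions delimiting the analysed portion of the upslope
DECILE_LO = 0.2
DECILE_HI = 0.8

#: relative tolerance used when checking time-grid uniformity
_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class VelocityCurve:
    """One plane's time-resolved mean velocity.

    Parameters
    ----------
    times : ndarray
        Sample times in ms, strictly increasing and uniformly spaced.
    velocities : ndarray
        Mean velocity at each sample, cm/s (or normalized units after
        :func:`normalize`).
    plane_index : int
        Index of the plane along the centerline (0 = upstream reference).
    distance_mm : float
        Arc-length distance from the reference plane, mm.
    """

    times: np.ndarray
    velocities: np.ndarray
    plane_index: int = 0
    distance_mm: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and velocities must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("a velocity curve needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=_GRID_RTOL, atol=1e-9):
            raise ValueError("times must be uniformly spaced")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "velocities", v)

    @property
    def dt(self) -> float:
        """Sample spacing in ms."""
        return float(self.times[1] - self.times[0])

    @property
    def n_samples(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class UpslopeWindow:
    """Landmarks of the systolic upslope of a normalized curve (all in ms)."""

    foot_time: float
    peak_time: float
    decile_lo_time: float
    decile_hi_time: float

    def __post_init__(self):
        if not (
            self.foot_time
            <= self.decile_lo_time
            < self.decile_hi_time
            <= self.peak_time
        ):
            raise ValueError(
                "upslope landmarks must be ordered foot <= 2nd decile < "
                "8th decile <= peak"
            )

    @property
    def rise_time(self) -> float:
        """Foot-to-peak duration in ms (t_rise)."""
        return self.peak_time - self.foot_time


def interpolate_1ms(curve: VelocityCurve) -> VelocityCurve:
    """Resample a curve to a 1-ms grid with a cubic spline.

    The spline passes exactly through the original samples (not-a-knot end
    conditions); the output grid spans the original time range.
    """
    if curve.n_samples < 4:
        raise ValueError("cubic spline interpolation needs at least 4 samples")
    spline = CubicSpline(curve.times, curve.velocities)
    t_new = np.arange(curve.times[0], curve.times[-1] + 0.5, 1.0)
    return replace(curve, times=t_new, velocities=spline(t_new))


def normalize(curve: VelocityCurve) -> VelocityCurve:
    """Min-max normalize velocities to [0, 1] over the full cycle."""
    v = curve.velocities
    vmin, vmax = float(v.min()), float(v.max())
    if vmax <= vmin:
        raise ValueError("cannot normalize a constant curve")
    return replace(curve, velocities=(v - vmin) / (vmax - vmin))


def _is_normalized(v: np.ndarray, atol: float = 1e-9) -> bool:
    return v.min() >= -atol and v.max() <= 1.0 + atol and (v.max() - v.min()) > 0.5


def _first_crossing(t: np.ndarray, v: np.ndarray, level: float) -> float:
    """Sub-sample time of the first upward crossing of ``level``.

    Linear interpolation between the bracketing grid samples.
    """
    idx = np.flatnonzero(v >= level)
    if idx.size == 0:
        raise ValueError(f"curve never reaches level {level}")
    i = int(idx[0])
    if i == 0:
        return float(t[0])
    v0, v1 = v[i - 1], v[i]
    return float(t[i - 1] + (level - v0) / (v1 - v0) * (t[i] - t[i - 1]))


def detect_systolic_upslope(
    curve: VelocityCurve,
    foot_threshold: float = FOOT_THRESHOLD,
    deciles: tuple[float, float] = (DECILE_LO, DECILE_HI),
) -> UpslopeWindow:
    """Locate foot, peak and 2nd/8th-decile crossings of a normalized curve.

    The peak is the earliest global maximum; the foot is the last time
    before the peak at which the curve is at or below ``foot_threshold``.
    Decile times are the first upward crossings of the two ``deciles``
    levels between foot and peak, localized to sub-ms precision by linear
    interpolation.  If the upslope is non-monotone the first crossings are
    used and a warning is emitted.
    """
    t, v = curve.times, curve.velocities
    if not _is_normalized(v):
        raise ValueError("detect_systolic_upslope expects a normalized curve")
    i_peak = int(np.argmax(v))
    if i_peak == 0:
        raise ValueError("curve peaks at its first sample; no systolic upslope")
    below = np.flatnonzero(v[: i_peak + 1] <= foot_threshold)
    i_foot = int(below[-1]) if below.size else 0
    seg_t = t[i_foot : i_peak + 1]
    seg_v = v[i_foot : i_peak + 1]
    if np.any(np.diff(seg_v) < 0):
        n_down = int(np.sum(np.diff(seg_v) < 0))
        warnings.warn(
            f"non-monotone systolic upslope ({n_down} decreasing steps); "
            "using first decile crossings",
            stacklevel=2,
        )
    lo = _first_crossing(seg_t, seg_v, deciles[0])
    hi = _first_crossing(seg_t, seg_v, deciles[1])
    return UpslopeWindow(
        foot_time=float(seg_t[0]),
        peak_time=float(t[i_peak]),
        decile_lo_time=lo,
        decile_hi_time=hi,
    )


def decile_segment(curve: VelocityCurve, window: UpslopeWindow) -> VelocityCurve:
    """Samples of the curve inside the closed 2nd-8th-decile window."""
    m = (curve.times >= window.decile_lo_time) & (
        curve.times <= window.decile_hi_time
    )
    if not np.any(m):
        raise ValueError("empty decile segment")
    return replace(curve, times=curve.times[m], velocities=curve.velocities[m])


def preprocess(curve: VelocityCurve) -> VelocityCurve:
    """Shared pipeline: interpolate to 1 ms then min-max normalize.

    Curves already sampled at 1 ms pass through the spline unchanged (the
    spline reproduces its own knots) and normalization is idempotent, so
    preprocessing an already-preprocessed curve is a no-op.
    """
    if curve.dt != 1.0:
        curve = interpolate_1ms(curve)
    return normalize(curve)
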