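"""Synthetic propagating-waveform generator with known true PWV.

Emulates the data a 4D-flow CMR exam provides for pulse wave velocity
analysis: a systolic velocity pulse travelling along the aortic centerline
at a known speed (typically 4-12 m/s), observed as mean-velocity waveforms
at a set of planes with known arc-length distances, sampled at 50 or 20
uniformly spaced frames over a ~1 s cardiac cycle, with additive Gaussian
noise and an optional backward-travelling reflected wave confined to the
late cycle.

Ground truth (the generating PWV and the exact per-plane arrival shifts)
is retained so estimators can be validated by parameter recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .preprocess import VelocityCurve

__all__ = [
    "TemplateWaveform",
    "PropagationSpec",
    "SyntheticTruth",
    "make_template",
    "template_value",
    "propagate",
    "sample_acquisition",
    "generate_cohort",
    "rasterize_field",
    "save_truths",
    "load_truths",
]

#: default plane layout: 25 planes equally spaced over 240 mm of centerline
DEFAULT_DISTANCES = tuple(float(d) for d in np.linspace(0.0, 240.0, 25))


@dataclass(frozen=True)
class TemplateWaveform:
    """Parametric single-cycle velocity waveform.

    The default shape is a half-cosine systolic upslope followed by an
    exponential diastolic decay: zero before the foot, monotone rise to the
    peak over ``t_rise`` and decay toward baseline afterwards.  Aortic mean
    velocity is near zero through most of diastole, hence the fairly short
    default decay constant.

    All times in ms, velocity in cm/s.
    """

    foot_time: float = 100.0
    t_rise: float = 80.0
    peak_velocity: float = 80.0
    decay_duration: float = 150.0
    cycle_length: float = 1000.0
    shape_name: str = "half-cosine-upslope"

    def __post_init__(self):
        if not 0.0 <= self.foot_time < self.foot_time + self.t_rise < self.cycle_length:
            raise ValueError(
                "need 0 <= foot_time < foot_time + t_rise < cycle_length"
            )
        if self.peak_velocity <= 0:
            raise ValueError("peak_velocity must be positive")
        if self.decay_duration <= 0:
            raise ValueError("decay_duration must be positive")
        if self.shape_name not in ("half-cosine-upslope", "gamma-pulse"):
            raise ValueError(f"unknown shape_name {self.shape_name!r}")


def template_value(params: TemplateWaveform, t: np.ndarray) -> np.ndarray:
    """Evaluate the template waveform at arbitrary times ``t`` (ms).

    Times outside [0, cycle_length) are evaluated as written (the waveform
    is zero before the foot), so a delayed copy can be produced simply by
    evaluating at ``t - delay``.
    """
    t = np.asarray(t, dtype=float)
    v = np.zeros_like(t)
    if params.shape_name == "half-cosine-upslope":
        u = t - params.foot_time
        on_rise = (u >= 0) & (u <= params.t_rise)
        v[on_rise] = (
            params.peak_velocity * 0.5 * (1.0 - np.cos(np.pi * u[on_rise] / params.t_rise))
        )
        after = u > params.t_rise
        v[after] = params.peak_velocity * np.exp(
            -(u[after] - params.t_rise) / params.decay_duration
        )
    else:  # gamma-pulse
        # gamma density shape with its mode at foot_time + t_rise; the scale
        # is tied to the decay duration so the tail relaxes over a similar
        # time span as the half-cosine template
        theta = params.decay_duration / 2.0
        k = 1.0 + params.t_rise / theta
        u = t - params.foot_time
        pos = u > 0
        mode = params.t_rise
        log_peak = (k - 1.0) * math.log(mode) - mode / theta
        v[pos] = params.peak_velocity * np.exp(
            (k - 1.0) * np.log(u[pos]) - u[pos] / theta - log_peak
        )
    return v


def make_template(params: TemplateWaveform) -> VelocityCurve:
    """Sample the template on a dense 1-ms grid over one cycle."""
    t = np.arange(0.0, params.cycle_length, 1.0)
    return VelocityCurve(times=t, velocities=template_value(params, t))


@dataclass(frozen=True)
class PropagationSpec:
    """How the template propagates and how it is observed.

    ``distances`` are arc-length positions (mm) of the observation planes
    measured from the upstream reference plane, strictly increasing from 0.
    A plane at distance D receives the template delayed by D / pwv_true ms
    (1 m/s = 1 mm/ms) and attenuated by (1 - attenuation_per_mm)**D.

    The optional reflected wave travels backward from beyond the most
    distal plane, so it reaches distal planes first:  its arrival at
    distance D is ``reflection_delay - D / pwv_true`` ms, with amplitude
    ``reflection_amplitude`` relative to the local forward wave.

    ``noise_sd`` is the standard deviation of additive Gaussian noise as a
    fraction of the reference-plane peak velocity (noise is a property of
    the acquisition, so its absolute level is the same at every plane).
    """

    pwv_true: float
    distances: tuple = DEFAULT_DISTANCES
    attenuation_per_mm: float = 0.0
    reflection_amplitude: float = 0.0
    reflection_delay: float = 300.0
    noise_sd: float = 0.0
    n_frames: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.pwv_true <= 0:
            raise ValueError("pwv_true must be positive")
        d = np.asarray(self.distances, dtype=float)
        if d.size < 2 or d[0] != 0.0 or np.any(np.diff(d) <= 0):
            raise ValueError("distances must strictly increase from 0")
        for name in ("attenuation_per_mm", "reflection_amplitude", "noise_sd"):
            val = getattr(self, name)
            if not 0.0 <= val < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.n_frames < 10:
            raise ValueError("n_frames must be at least 10")
        object.__setattr__(self, "distances", tuple(float(x) for x in d))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth attached to a generated waveform set."""

    pwv_true: float
    arrival_shifts: tuple  # per-plane true arrival shift, ms
    spec: PropagationSpec

    def __post_init__(self):
        expected = tuple(d / self.pwv_true for d in self.spec.distances)
        if not np.allclose(self.arrival_shifts, expected):
            raise ValueError("arrival_shifts must equal distances / pwv_true")


def propagate(
    template: TemplateWaveform, spec: PropagationSpec
) -> tuple[list[VelocityCurve], SyntheticTruth]:
    """Dense (1-ms) noise-free waveforms at every plane, plus ground truth."""
    t = np.arange(0.0, template.cycle_length, 1.0)
    curves = []
    for i, d in enumerate(spec.distances):
        shift = d / spec.pwv_true  # mm / (mm/ms) = ms
        amp = (1.0 - spec.attenuation_per_mm) ** d
        v = amp * template_value(template, t - shift)
        if spec.reflection_amplitude > 0:
            refl_arrival = spec.reflection_delay - shift
            v = v + amp * spec.reflection_amplitude * template_value(
                template, t - refl_arrival
            )
        curves.append(
            VelocityCurve(times=t, velocities=v, plane_index=i, distance_mm=d)
        )
    truth = SyntheticTruth(
        pwv_true=spec.pwv_true,
        arrival_shifts=tuple(d / spec.pwv_true for d in spec.distances),
        spec=spec,
    )
    return curves, truth


def sample_acquisition(
    dense_curves: list[VelocityCurve],
    n_frames: int,
    noise_sd: float,
    seed: int,
    cycle_length: float | None = None,
) -> list[VelocityCurve]:
    """Sample dense curves at acquisition temporal resolution and add noise.

    The cycle is divided into ``n_frames`` uniform frames (spacing
    cycle_length / n_frames, first frame at t = 0).  I.i.d. Gaussian noise
    with sd = noise_sd x reference-plane peak velocity is added to every
    sample.  Bit-identical output under an identical seed.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be at least 10")
    if cycle_length is None:
        c0 = dense_curves[0]
        cycle_length = float(c0.times[-1] - c0.times[0] + c0.dt)
    frame_times = np.arange(n_frames) * cycle_length / n_frames
    rng = np.random.default_rng(seed)
    ref_peak = float(dense_curves[0].velocities.max())
    out = []
    for c in dense_curves:
        v = np.interp(frame_times, c.times, c.velocities)
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd * ref_peak, size=n_frames)
        out.append(
            VelocityCurve(
                times=frame_times,
                velocities=v,
                plane_index=c.plane_index,
                distance_mm=c.distance_mm,
            )
        )
    return out


@dataclass(frozen=True)
class Subject:
    """One synthetic subject: acquisition-resolution curves plus truth."""

    subject_id: str
    curves: list
    truth: SyntheticTruth


def generate_cohort(
    n_subjects: int,
    pwv_range: tuple[float, float] = (4.0, 12.0),
    template: TemplateWaveform | None = None,
    distances: tuple = DEFAULT_DISTANCES,
    attenuation_per_mm: float = 0.0,
    reflection_amplitude: float = 0.0,
    reflection_delay: float = 300.0,
    noise_sd: float = 0.0,
    n_frames: int = 50,
    seed: int = 0,
) -> list[Subject]:
    """Generate a reproducible cohort with per-subject true PWV.

    True PWV is drawn uniformly from ``pwv_range``; each subject gets an
    independent child seed spawned from ``seed`` so cohorts of different
    sizes share their leading subjects.
    """
    lo, hi = pwv_range
    if not (1.0 < lo <= hi < 20.0):
        raise ValueError("pwv_range must lie within (1, 20) m/s")
    if template is None:
        template = TemplateWaveform()
    root = np.random.SeedSequence(seed)
    subjects = []
    for k, child in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        pwv = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        noise_seed = int(rng.integers(0, 2**31 - 1))
        spec = PropagationSpec(
            pwv_true=pwv,
            distances=distances,
            attenuation_per_mm=attenuation_per_mm,
            reflection_amplitude=reflection_amplitude,
            reflection_delay=reflection_delay,
            noise_sd=noise_sd,
            n_frames=n_frames,
            seed=noise_seed,
        )
        dense, truth = propagate(template, spec)
        curves = sample_acquisition(
            dense, n_frames, noise_sd, noise_seed, template.cycle_length
        )
        subjects.append(Subject(subject_id=f"sub{k:03d}", curves=curves, truth=truth))
    return subjects


# ---------------------------------------------------------------------------
# Gridded-field rasterization (enables end-to-end testing of field extraction)
# ---------------------------------------------------------------------------


def rasterize_field(
    curves: list[VelocityCurve],
    centerline_points: np.ndarray,
    tube_radius_mm: float,
    voxel_size_mm: float = 2.0,
    margin_voxels: int = 2,
    noise_sd_cm_s: float = 0.0,
    seed: int = 0,
):
    """Rasterize plane waveforms into a gridded time-resolved velocity field.

    Each within-lumen voxel (distance to the centerline polyline below
    ``tube_radius_mm``) carries the velocity of the nearest plane (by
    arc-length), directed along the local centerline tangent.  Voxels
    outside the lumen carry only noise.  Returns a
    :class:`~aopwv.field.VelocityField`.
    """
    from .field import VelocityField, arc_length

    if tube_radius_mm < 2.0 * voxel_size_mm:
        raise ValueError("tube radius must be at least 2 voxels")
    pts = np.asarray(centerline_points, dtype=float)
    arc = arc_length(pts)
    # unit tangents along the polyline (central differences)
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    pad = tube_radius_mm + margin_voxels * voxel_size_mm
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    shape = np.ceil((hi - lo) / voxel_size_mm).astype(int)
    idx = np.stack(
        np.meshgrid(*(np.arange(s) for s in shape), indexing="ij"), axis=-1
    )
    centers = lo + (idx + 0.5) * voxel_size_mm  # (X, Y, Z, 3)

    flat = centers.reshape(-1, 3)
    # distance from every voxel center to the centerline polyline, plus the
    # arc-length of the closest point (segment-wise projection)
    a, b = pts[:-1], pts[1:]
    ab = b - a
    ab2 = np.einsum("ij,ij->i", ab, ab)
    best_d2 = np.full(flat.shape[0], np.inf)
    best_arc = np.zeros(flat.shape[0])
    for s in range(len(a)):
        ap = flat - a[s]
        tpar = np.clip(np.einsum("ij,j->i", ap, ab[s]) / ab2[s], 0.0, 1.0)
        proj = a[s] + tpar[:, None] * ab[s]
        d2 = np.einsum("ij,ij->i", flat - proj, flat - proj)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_arc[closer] = arc[s] + tpar[closer] * np.sqrt(ab2[s])
    in_lumen = (best_d2 <= tube_radius_mm**2).reshape(shape)

    plane_arcs = np.array([c.distance_mm for c in curves])
    nearest_plane = np.argmin(
        np.abs(best_arc[:, None] - plane_arcs[None, :]), axis=1
    ).reshape(shape)
    # local tangent direction for each voxel: tangent at closest polyline point
    seg_arc_mid = 0.5 * (arc[:-1] + arc[1:])
    nearest_seg = np.clip(
        np.searchsorted(seg_arc_mid, best_arc), 0, len(pts) - 1
    ).reshape(shape)

    frame_times = curves[0].times
    n_t = frame_times.size
    vel = np.zeros((n_t,) + tuple(shape) + (3,))
    wave = np.stack([c.velocities for c in curves])  # (n_planes, n_t)
    lum_idx = np.argwhere(in_lumen)
    for i, j, k in lum_idx:
        tang = tangents[nearest_seg[i, j, k]]
        vel[:, i, j, k, :] = wave[nearest_plane[i, j, k]][:, None] * tang[None, :]
    if noise_sd_cm_s > 0:
        rng = np.random.default_rng(seed)
        vel = vel + rng.normal(0.0, noise_sd_cm_s, size=vel.shape)
    modulus = np.ones((n_t,) + tuple(shape))
    return VelocityField(
        velocity=vel,
        modulus=modulus,
        mask=in_lumen,
        voxel_size_mm=float(voxel_size_mm),
        frame_times_ms=np.asarray(frame_times, dtype=float),
        origin_mm=lo,
    )


# ---------------------------------------------------------------------------
# Truth sidecar serialization
# ---------------------------------------------------------------------------


def save_truths(path: str | Path, subjects: list[Subject]) -> None:
    """Write ground truths of a cohort as a JSON sidecar."""
    payload = {}
    for s in subjects:
        d = asdict(s.truth)
        d["spec"]["distances"] = list(d["spec"]["distances"])
        d["arrival_shifts"] = list(d["arrival_shifts"])
        payload[s.subject_id] = d
    Path(path).write_text(json.dumps(payload, indent=1))


def load_truths(path: str | Path) -> dict[str, SyntheticTruth]:
    """Read a truth sidecar written by :func:`save_truths`."""
    raw = json.loads(Path(path).read_text())
    out = {}
    for sid, d in raw.items():
        spec = PropagationSpec(**{**d["spec"], "distances": tuple(d["spec"]["distances"])})
        out[sid] = SyntheticTruth(
            pwv_true=d["pwv_true"],
            arrival_shifts=tuple(d["arrival_shifts"]),
            spec=spec,
        )
    return out
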