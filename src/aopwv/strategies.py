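"""PWV estimation strategies combining plane distances and waveforms.

Strategy 1 (S1, two-plane): PWV = D / TT between the two extreme planes.
Strategy 2 (S2, iterative fit): TT_i is estimated between the reference
    plane and every other plane; a linear fit TT_i = a D_i + b gives
    PWV = 1/a.
Strategy 3 (S3, plane fitting): all (distance, time, velocity) samples of
    the 2nd-8th-decile systolic upslopes are pooled and fitted with the
    plane v = alpha t + beta d + gamma; a pure traveling wave
    v = s (t - d/c) has alpha = s and beta = -s/c, so PWV = -alpha/beta.

The Cramer-Rao lower bound on the PWV standard error, given temporal and
spatial resolution, SNR and vessel length, is provided as a utility.

Units: distances mm, times ms, PWV m/s (1 mm/ms = 1 m/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import VelocityCurve, decile_segment, detect_systolic_upslope, preprocess
from .transit import TransitTimeError, estimate_tt

__all__ = [
    "PWVEstimate",
    "EstimationError",
    "CRLBParams",
    "pwv_two_plane",
    "pwv_iterative_fit",
    "pwv_plane_fit",
    "crlb_bound",
    "ESTIMATORS",
    "estimate_all",
]


class EstimationError(ValueError):
    """A PWV estimate could not be produced; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class PWVEstimate:
    """A pulse wave velocity estimate in m/s with fit diagnostics."""

    value: float
    strategy: str
    tt_method: str | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isfinite(self.value) and self.value > 0):
            raise EstimationError(
                f"PWV estimate must be positive and finite, got {self.value}",
                dict(self.diagnostics),
            )

    @property
    def label(self) -> str:
        return f"{self.strategy}-{self.tt_method}" if self.tt_method else self.strategy


def pwv_two_plane(
    proximal: VelocityCurve,
    distal: VelocityCurve,
    distance_mm: float | None = None,
    tt_method: str = "ttw",
    **tt_kwargs,
) -> PWVEstimate:
    """Strategy 1: PWV = D / TT between two planes.

    ``proximal`` is the upstream curve (wave arrives first).  The distance
    defaults to the difference of the curves' ``distance_mm`` attributes.
    """
    if distance_mm is None:
        distance_mm = distal.distance_mm - proximal.distance_mm
    if distance_mm <= 0:
        raise EstimationError("plane separation must be positive")
    tt = estimate_tt(proximal, distal, tt_method, **tt_kwargs)
    if tt.value <= 0 or not np.isfinite(tt.value):
        raise EstimationError(
            f"non-positive transit time {tt.value:.2f} ms",
            {"tt": tt.value, "tt_diagnostics": tt.diagnostics},
        )
    return PWVEstimate(
        value=distance_mm / tt.value,  # mm/ms = m/s
        strategy="S1",
        tt_method=tt.method,
        diagnostics={"D_mm": float(distance_mm), "TT_ms": tt.value,
                     **{f"tt_{k}": v for k, v in tt.diagnostics.items()}},
    )


def pwv_iterative_fit(
    curves: list[VelocityCurve],
    tt_method: str = "ttw",
    through_origin: bool = False,
    robust: bool = False,
    **tt_kwargs,
) -> PWVEstimate:
    """Strategy 2: iterative transit times regressed against distance.

    TT_i is estimated between the reference plane (``curves[0]``, the
    upstream end) and each successive plane; ordinary least squares
    TT_i = a D_i + b yields PWV = 1/a.  Pairs whose TT estimation fails
    are dropped (at least 3 must survive).  ``through_origin`` forces
    b = 0; ``robust`` replaces OLS with a Theil-Sen fit.
    """
    if len(curves) < 3:
        raise EstimationError("strategy 2 needs at least 3 planes")
    ref = curves[0]
    D, TT, dropped = [], [], 0
    for c in curves[1:]:
        try:
            tt = estimate_tt(ref, c, tt_method, **tt_kwargs)
        except (TransitTimeError, ValueError):
            dropped += 1
            continue
        D.append(c.distance_mm - ref.distance_mm)
        TT.append(tt.value)
    if len(D) < 3:
        raise EstimationError(
            f"only {len(D)} usable (D, TT) pairs after {dropped} failures"
        )
    D = np.asarray(D)
    TT = np.asarray(TT)
    if through_origin:
        a = float(np.dot(D, TT) / np.dot(D, D))
        b = 0.0
        ss_res = float(np.sum((TT - a * D) ** 2))
        ss_tot = float(np.sum((TT - TT.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    elif robust:
        res = stats.theilslopes(TT, D)
        a, b = float(res.slope), float(res.intercept)
        r2 = float(np.corrcoef(D, TT)[0, 1] ** 2)
    else:
        fit = stats.linregress(D, TT)
        a, b = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue**2)
    if a <= 0:
        raise EstimationError(
            f"non-positive TT-vs-D slope {a:.4f} ms/mm",
            {"slope": a, "intercept": b, "r2": r2},
        )
    tt_name = {"ttc": "TTc", "ttw": "TTw", "ttf": "TTf", "oracle": "oracle"}[
        tt_method.lower()
    ]
    return PWVEstimate(
        value=1.0 / a,  # (ms/mm)^-1 = mm/ms = m/s
        strategy="S2",
        tt_method=tt_name,
        diagnostics={
            "slope_ms_per_mm": a,
            "intercept_ms": b,
            "r_squared": r2,
            "n_pairs": int(len(D)),
            "n_dropped": int(dropped),
        },
    )


def pwv_plane_fit(curves: list[VelocityCurve], tls: bool = False) -> PWVEstimate:
    """Strategy 3: plane fit of pooled systolic-upslope samples.

    Pools every (d_i, t, v) sample of the 2nd-8th-decile upslope segment of
    every plane and fits v = alpha t + beta d + gamma by least squares on
    v (the noisy measured quantity).  PWV = -alpha/beta.  ``tls`` switches
    to a total-least-squares fit of the implicit plane
    a d + b t + c v + e = 0 (smallest singular vector).
    """
    if len(curves) < 3:
        raise EstimationError("strategy 3 needs at least 3 planes")
    d_all, t_all, v_all = [], [], []
    for c in curves:
        cc = preprocess(c)
        seg = decile_segment(cc, detect_systolic_upslope(cc))
        d_all.append(np.full(seg.n_samples, cc.distance_mm))
        t_all.append(seg.times)
        v_all.append(seg.velocities)
    d = np.concatenate(d_all)
    t = np.concatenate(t_all)
    v = np.concatenate(v_all)
    if np.ptp(d) == 0 or np.ptp(t) == 0:
        raise EstimationError("degenerate design: no spread in distance or time")
    if tls:
        M = np.column_stack([d, t, v, np.ones_like(v)])
        M0 = M - M.mean(axis=0)
        _, _, vh = np.linalg.svd(M0[:, :3], full_matrices=False)
        a_d, a_t, a_v = vh[-1]
        if a_v == 0:
            raise EstimationError("degenerate TLS plane (vertical in v)")
        alpha, beta = -a_t / a_v, -a_d / a_v
        resid_rms = float(np.sqrt(np.mean((M0[:, :3] @ vh[-1]) ** 2)))
    else:
        M = np.column_stack([t, d, np.ones_like(v)])
        coef, _, _, _ = np.linalg.lstsq(M, v, rcond=None)
        alpha, beta, _gamma = (float(c) for c in coef)
        resid_rms = float(np.sqrt(np.mean((M @ coef - v) ** 2)))
    if beta >= 0:
        raise EstimationError(
            f"non-negative distance coefficient beta={beta:.5f}; no forward "
            "wave propagation detected",
            {"alpha": alpha, "beta": beta},
        )
    return PWVEstimate(
        value=-alpha / beta,  # mm/ms = m/s
        strategy="S3",
        tt_method=None,
        diagnostics={
            "alpha_per_ms": float(alpha),
            "beta_per_mm": float(beta),
            "residual_rms": resid_rms,
            "n_samples": int(v.size),
        },
    )


# -- Cramer-Rao lower bound --------------------------------------------------


@dataclass(frozen=True)
class CRLBParams:
    """Inputs of the Cramer-Rao lower bound on the PWV standard error.

    c : PWV estimate, m/s
    snr : signal-to-noise ratio (dimensionless)
    phi_max : phase angle at maximal velocity, rad
    dt : temporal resolution, s
    dx : spatial resolution, m
    t_rise : systolic upslope duration, s
    length : vessel length covered, m
    """

    c: float
    snr: float
    phi_max: float
    dt: float
    dx: float
    t_rise: float
    length: float

    def __post_init__(self):
        for name in ("c", "snr", "phi_max", "dt", "dx", "t_rise", "length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def crlb_bound(params: CRLBParams) -> float:
    """Lower bound sigma_c (m/s) on the PWV estimation error.

    sigma_c = c^2 / (SNR phi_max) * sqrt(6 dt dx t_rise / L^3).

    The bound shrinks as L^(3/2): covering a longer vessel is the most
    effective way to reduce PWV error at fixed resolution and SNR.
    """
    p = params
    return (p.c**2 / (p.snr * p.phi_max)) * math.sqrt(
        6.0 * p.dt * p.dx * p.t_rise / p.length**3
    )


# -- the seven-estimator battery ---------------------------------------------

ESTIMATORS = [
    ("S1", "ttc"),
    ("S1", "ttw"),
    ("S1", "ttf"),
    ("S2", "ttc"),
    ("S2", "ttw"),
    ("S2", "ttf"),
    ("S3", None),
]


def estimate_all(curves: list[VelocityCurve]) -> dict[str, PWVEstimate | EstimationError]:
    """Run all seven estimators on one subject's plane set.

    Returns a mapping from estimator label ('S1-TTc' ... 'S3') to either a
    :class:`PWVEstimate` or the :class:`EstimationError` that occurred, so
    cohort summaries can count usable cases.
    """
    names = {"ttc": "TTc", "ttw": "TTw", "ttf": "TTf"}
    out: dict[str, PWVEstimate | EstimationError] = {}
    for strategy, ttm in ESTIMATORS:
        label = f"{strategy}-{names[ttm]}" if ttm else strategy
        try:
            if strategy == "S1":
                out[label] = pwv_two_plane(curves[0], curves[-1], tt_method=ttm)
            elif strategy == "S2":
                out[label] = pwv_iterative_fit(curves, tt_method=ttm)
            else:
                out[label] = pwv_plane_fit(curves)
        except (EstimationError, TransitTimeError) as err:
            out[label] = err if isinstance(err, EstimationError) else EstimationError(str(err))
    return out
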