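"""Waveform CSV I/O and run configuration.

Waveform sets travel as long-format CSV with columns ``subject_id``,
``plane_index``, ``distance_mm``, ``time_ms``, ``velocity_cm_s`` — diffable
and language-neutral.  Gridded fields use NPZ (see
:meth:`aopwv.field.VelocityField.save_npz`).  The run configuration is a
YAML-serializable dataclass holding every tunable of the pipeline exactly
once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import VelocityCurve

__all__ = ["read_waveforms", "write_waveforms", "RunConfig"]

WAVEFORM_COLUMNS = [
    "subject_id",
    "plane_index",
    "distance_mm",
    "time_ms",
    "velocity_cm_s",
]


def write_waveforms(path: str | Path, subjects: dict[str, list[VelocityCurve]]) -> None:
    """Write subject waveform sets as long-format CSV."""
    rows = []
    for sid, curves in subjects.items():
        for c in curves:
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "plane_index": c.plane_index,
                        "distance_mm": c.distance_mm,
                        "time_ms": c.times,
                        "velocity_cm_s": c.velocities,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_waveforms(path: str | Path) -> dict[str, list[VelocityCurve]]:
    """Read and validate a waveform CSV into per-subject curve lists.

    Rows may appear in any order; curves are grouped by subject and plane,
    sorted by time, and checked for uniform time grids and strictly
    increasing plane distances.
    """
    df = pd.read_csv(path)
    missing = set(WAVEFORM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"waveform CSV is missing columns {sorted(missing)}")
    out: dict[str, list[VelocityCurve]] = {}
    for sid, sgroup in df.groupby("subject_id", sort=True):
        curves = []
        for pidx, pgroup in sgroup.groupby("plane_index", sort=True):
            pgroup = pgroup.sort_values("time_ms")
            t = pgroup["time_ms"].to_numpy(dtype=float)
            dt = np.diff(t)
            if t.size < 2 or np.any(dt <= 0):
                raise ValueError(
                    f"subject {sid} plane {pidx}: non-increasing time grid"
                )
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                bad = int(np.argmax(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-9)))
                row = int(pgroup.index[bad + 1])
                raise ValueError(
                    f"subject {sid} plane {pidx}: non-uniform time grid "
                    f"(gap after row {row})"
                )
            dist = pgroup["distance_mm"].to_numpy(dtype=float)
            if np.ptp(dist) != 0:
                raise ValueError(
                    f"subject {sid} plane {pidx}: inconsistent distance_mm"
                )
            curves.append(
                VelocityCurve(
                    times=t,
                    velocities=pgroup["velocity_cm_s"].to_numpy(dtype=float),
                    plane_index=int(pidx),
                    distance_mm=float(dist[0]),
                )
            )
        d = [c.distance_mm for c in curves]
        if np.any(np.diff(d) <= 0):
            raise ValueError(f"subject {sid}: plane distances are not increasing")
        out[str(sid)] = curves
    return out


@dataclass
class RunConfig:
    """Every tunable of the simulate -> estimate -> compare pipeline.

    Round-trips through YAML: ``RunConfig.load(p)`` after ``save(p)``
    reproduces the instance exactly.
    """

    # cohort simulation
    n_subjects: int = 20
    pwv_range: tuple = (4.0, 12.0)
    n_planes: int = 25
    centerline_length_mm: float = 240.0
    template_foot_time: float = 100.0
    template_t_rise: float = 80.0
    template_peak_velocity: float = 80.0
    template_decay_duration: float = 150.0
    template_cycle_length: float = 1000.0
    template_shape: str = "half-cosine-upslope"
    attenuation_per_mm: float = 0.0
    reflection_amplitude: float = 0.2
    reflection_delay: float = 300.0
    noise_sd: float = 0.05
    frame_counts: tuple = (50, 20)
    seed: int = 0
    # preprocessing
    foot_threshold: float = 0.05
    decile_lo: float = 0.2
    decile_hi: float = 0.8
    # transit-time options
    ttc_refine: bool = True
    ttw_freq_min_hz: float = 0.5
    ttw_freq_max_hz: float = 15.0
    ttw_n_scales: int = 32
    ttf_max_freq_hz: float = 10.0
    ttf_weight: str = "power"
    # strategy options
    s2_robust: bool = False
    s3_tls: bool = False
    # output
    output_dir: str = "aopwv_results"

    def save(self, path: str | Path) -> None:
        d = asdict(self)
        d["pwv_range"] = list(self.pwv_range)
        d["frame_counts"] = list(self.frame_counts)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["pwv_range"] = tuple(d["pwv_range"])
        d["frame_counts"] = tuple(d["frame_counts"])
        return cls(**d)
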