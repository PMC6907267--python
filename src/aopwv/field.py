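"""Gridded 4D velocity fields: PC-MRA, centerline planes, curve extraction.

Operates on a time-resolved 3D velocity field with a static lumen mask (as
produced by a 4D-flow reconstruction after segmentation, or by
:func:`aopwv.synthetic.rasterize_field`).  Provides the angiographic
PC-MRA volume, centerline arc-lengths, placement of equally spaced planes
perpendicular to the centerline, and per-plane mean through-plane velocity
curves.

Coordinates are continuous mm; voxel centers sit at (index + 0.5) x voxel
size relative to the field origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import VelocityCurve

__all__ = [
    "VelocityField",
    "Centerline",
    "PlaneSampling",
    "compute_pcmra",
    "arc_length",
    "place_planes",
    "extract_mean_velocity",
    "extract_all_planes",
]


@dataclass(frozen=True)
class VelocityField:
    """Time-resolved gridded velocity data.

    velocity : (T, X, Y, Z, 3) array, cm/s
    modulus : (T, X, Y, Z) signal-magnitude array (arbitrary units)
    mask : (X, Y, Z) boolean static lumen mask
    voxel_size_mm : isotropic voxel edge length
    frame_times_ms : (T,) frame times
    origin_mm : world coordinate of the grid corner (voxel [0,0,0] corner)
    """

    velocity: np.ndarray
    modulus: np.ndarray
    mask: np.ndarray
    voxel_size_mm: float
    frame_times_ms: np.ndarray
    origin_mm: np.ndarray = None

    def __post_init__(self):
        if self.origin_mm is None:
            object.__setattr__(self, "origin_mm", np.zeros(3))
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise ValueError("velocity must have shape (T, X, Y, Z, 3)")
        if self.mask.shape != self.velocity.shape[1:4]:
            raise ValueError("mask shape must match the spatial grid")

    def voxel_centers(self) -> np.ndarray:
        """(X, Y, Z, 3) world coordinates of voxel centers, mm."""
        idx = np.stack(
            np.meshgrid(*(np.arange(s) for s in self.mask.shape), indexing="ij"),
            axis=-1,
        )
        return self.origin_mm + (idx + 0.5) * self.voxel_size_mm

    def save_npz(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            velocity=self.velocity,
            modulus=self.modulus,
            mask=self.mask,
            voxel_size_mm=self.voxel_size_mm,
            frame_times_ms=self.frame_times_ms,
            origin_mm=self.origin_mm,
        )

    @classmethod
    def load_npz(cls, path: str | Path) -> "VelocityField":
        with np.load(path) as z:
            return cls(
                velocity=z["velocity"],
                modulus=z["modulus"],
                mask=z["mask"].astype(bool),
                voxel_size_mm=float(z["voxel_size_mm"]),
                frame_times_ms=z["frame_times_ms"],
                origin_mm=z["origin_mm"],
            )


@dataclass(frozen=True)
class Centerline:
    """Ordered 3D centerline points (mm) with cumulative arc-length."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("centerline needs >= 2 points of shape (N, 3)")
        object.__setattr__(self, "points", pts)

    @property
    def arc(self) -> np.ndarray:
        return arc_length(self.points)

    @property
    def length_mm(self) -> float:
        return float(self.arc[-1])


@dataclass(frozen=True)
class PlaneSampling:
    """Equally spaced planes perpendicular to a centerline.

    origins : (N, 3) plane origins, mm
    normals : (N, 3) unit normals (local centerline tangents)
    distances : (N,) arc-length from the first plane, mm (D_1 = 0)
    """

    origins: np.ndarray
    normals: np.ndarray
    distances: np.ndarray

    def __post_init__(self):
        if not np.allclose(np.linalg.norm(self.normals, axis=1), 1.0, atol=1e-8):
            raise ValueError("plane normals must be unit length")
        if self.distances[0] != 0.0 or np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must strictly increase from 0")

    @property
    def n_planes(self) -> int:
        return int(self.distances.size)


def compute_pcmra(
    field: VelocityField, window_halfwidth: int = 2
) -> np.ndarray:
    """Phase-contrast MR angiogram: modulus x speed averaged around peak systole.

    The systolic window is the temporal phase with maximal in-mask speed,
    plus/minus ``window_halfwidth`` frames (clipped to the cycle).  Returns
    a non-negative 3D scalar volume.
    """
    speed = np.linalg.norm(field.velocity, axis=-1)  # (T, X, Y, Z)
    if field.mask.any():
        in_mask_peak = speed[:, field.mask].max(axis=1)
    else:
        in_mask_peak = speed.reshape(speed.shape[0], -1).max(axis=1)
    t_peak = int(np.argmax(in_mask_peak))
    lo = max(0, t_peak - window_halfwidth)
    hi = min(speed.shape[0], t_peak + window_halfwidth + 1)
    if hi <= lo:
        raise ValueError("empty systolic window")
    return np.mean(field.modulus[lo:hi] * speed[lo:hi], axis=0)


def arc_length(points: np.ndarray) -> np.ndarray:
    """Cumulative piecewise-linear chord length of an ordered point path."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def place_planes(centerline: Centerline, n: int = 25) -> PlaneSampling:
    """Place ``n`` planes at equal arc-length fractions along a centerline.

    Plane i sits at arc-length fraction i/(n-1); its normal is the local
    tangent obtained by central differences of the resampled origins.
    """
    if n < 2:
        raise ValueError("need at least 2 planes")
    arc = centerline.arc
    targets = np.linspace(0.0, arc[-1], n)
    origins = np.column_stack(
        [np.interp(targets, arc, centerline.points[:, k]) for k in range(3)]
    )
    tangents = np.gradient(origins, targets, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return PlaneSampling(origins=origins, normals=tangents, distances=targets)


def extract_mean_velocity(
    field: VelocityField,
    origin: np.ndarray,
    normal: np.ndarray,
    plane_index: int = 0,
    distance_mm: float = 0.0,
) -> VelocityCurve:
    """Mean through-plane velocity over the in-mask slab of one plane.

    Slab membership: |signed distance of the voxel center to the plane| at
    most half the voxel diagonal.  Velocity is projected onto the plane
    normal before averaging.
    """
    centers = field.voxel_centers()
    signed = np.einsum("xyzk,k->xyz", centers - np.asarray(origin), normal)
    half_diag = 0.5 * field.voxel_size_mm * np.sqrt(3.0)
    slab = field.mask & (np.abs(signed) <= half_diag)
    if not slab.any():
        raise ValueError(f"plane {plane_index} does not intersect the lumen mask")
    proj = np.einsum("txyzk,k->txyz", field.velocity, normal)
    mean_v = proj[:, slab].mean(axis=1)
    return VelocityCurve(
        times=field.frame_times_ms,
        velocities=mean_v,
        plane_index=plane_index,
        distance_mm=distance_mm,
    )


def extract_all_planes(
    field: VelocityField, planes: PlaneSampling
) -> list[VelocityCurve]:
    """Mean-velocity curves for every plane of a :class:`PlaneSampling`."""
    return [
        extract_mean_velocity(
            field,
            planes.origins[i],
            planes.normals[i],
            plane_index=i,
            distance_mm=float(planes.distances[i]),
        )
        for i in range(planes.n_planes)
    ]
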