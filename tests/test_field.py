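"""Field extraction: PC-MRA, arc length, plane placement, curve extraction."""

import numpy as np
import pytest

from aopwv import (
    Centerline,
    PropagationSpec,
    TemplateWaveform,
    VelocityField,
    arc_length,
    compute_pcmra,
    extract_all_planes,
    extract_mean_velocity,
    place_planes,
    propagate,
    rasterize_field,
    sample_acquisition,
)


class TestArcLength:
    def test_collinear_points(self):
        pts = np.array([[0, 0, 0], [3, 0, 0], [7, 0, 0]], dtype=float)
        np.testing.assert_allclose(arc_length(pts), [0, 3, 7])

    def test_unit_square_path(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        np.testing.assert_allclose(arc_length(pts), [0, 1, 2, 3])

    def test_helix_against_closed_form(self):
        """Chord-sum of a dense helix matches r*sqrt(1+(b/r)^2)*theta."""
        r, b = 10.0, 3.0
        theta = np.linspace(0, 4 * np.pi, 4000)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), b * theta])
        exact = 4 * np.pi * np.hypot(r, b)
        assert arc_length(pts)[-1] == pytest.approx(exact, rel=1e-3)

    def test_duplicate_points_allowed(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        np.testing.assert_allclose(arc_length(pts), [0, 1, 1, 2])


def curved_centerline(length_mm=240.0, n=241):
    """Gentle circular arc in the x-z plane with total arc length ``length_mm``."""
    radius = 400.0
    theta = np.linspace(0.0, length_mm / radius, n)
    return np.column_stack(
        [radius * np.sin(theta), np.zeros(n), radius * (1 - np.cos(theta))]
    )


class TestPlacePlanes:
    def test_straight_line_uniform_spacing(self):
        pts = np.column_stack([np.linspace(0, 240, 25), np.zeros(25), np.zeros(25)])
        planes = place_planes(Centerline(pts), 25)
        np.testing.assert_allclose(np.diff(planes.distances), 10.0)
        np.testing.assert_allclose(planes.normals, [[1.0, 0, 0]] * 25, atol=1e-12)

    def test_two_planes_are_endpoints(self):
        pts = np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0]], dtype=float)
        planes = place_planes(Centerline(pts), 2)
        np.testing.assert_allclose(planes.origins, [[0, 0, 0], [10, 0, 0]])

    def test_curved_tube_normals_match_analytic_tangent(self):
        pts = curved_centerline()
        planes = place_planes(Centerline(pts), 25)
        radius = 400.0
        for origin, normal in zip(planes.origins, planes.normals):
            theta = np.arcsin(np.clip(origin[0] / radius, -1, 1))
            analytic = np.array([np.cos(theta), 0.0, np.sin(theta)])
            assert np.dot(normal, analytic) > 0.99

    def test_too_few_planes_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            place_planes(Centerline(pts), 1)


@pytest.fixture(scope="module")
def tube_field():
    """Small rasterized curved-tube field at 6 m/s (noiseless, 50 frames)."""
    pts = curved_centerline()
    spec = PropagationSpec(pwv_true=6.0)
    dense, truth = propagate(TemplateWaveform(), spec)
    acq = sample_acquisition(dense, 50, 0.0, 0)
    fld = rasterize_field(acq, pts, tube_radius_mm=5.0, voxel_size_mm=2.0)
    return fld, pts, acq, truth


class TestPcmra:
    def test_zero_velocity_gives_zero_volume(self):
        vel = np.zeros((5, 4, 4, 4, 3))
        mod = np.ones((5, 4, 4, 4))
        mask = np.ones((4, 4, 4), dtype=bool)
        fld = VelocityField(vel, mod, mask, 1.0, np.arange(5.0) * 20)
        np.testing.assert_array_equal(compute_pcmra(fld), 0.0)

    def test_single_frame_window_equals_speed_map(self):
        rng = np.random.default_rng(0)
        vel = rng.normal(size=(1, 3, 3, 3, 3))
        mod = np.ones((1, 3, 3, 3))
        mask = np.ones((3, 3, 3), dtype=bool)
        fld = VelocityField(vel, mod, mask, 1.0, np.array([0.0]))
        np.testing.assert_allclose(
            compute_pcmra(fld, window_halfwidth=0),
            np.linalg.norm(vel[0], axis=-1),
        )

    def test_lumen_contrast_on_tube_fixture(self, tube_field):
        fld, *_ = tube_field
        pcmra = compute_pcmra(fld)
        inside = pcmra[fld.mask].mean()
        outside = pcmra[~fld.mask].mean() + 1e-12
        assert inside > 5 * outside


class TestExtractMeanVelocity:
    def test_uniform_axial_velocity_recovered(self):
        vel = np.zeros((3, 8, 4, 4, 3))
        vel[..., 0] = 50.0
        mask = np.ones((8, 4, 4), dtype=bool)
        fld = VelocityField(vel, np.ones((3, 8, 4, 4)), mask, 1.0, np.arange(3.0))
        c = extract_mean_velocity(fld, origin=[4.0, 2.0, 2.0], normal=[1.0, 0, 0])
        np.testing.assert_allclose(c.velocities, 50.0)

    def test_orthogonal_velocity_projects_to_zero(self):
        vel = np.zeros((3, 8, 4, 4, 3))
        vel[..., 1] = 30.0
        mask = np.ones((8, 4, 4), dtype=bool)
        fld = VelocityField(vel, np.ones((3, 8, 4, 4)), mask, 1.0, np.arange(3.0))
        c = extract_mean_velocity(fld, origin=[4.0, 2.0, 2.0], normal=[1.0, 0, 0])
        np.testing.assert_allclose(c.velocities, 0.0, atol=1e-12)

    def test_plane_outside_mask_rejected(self):
        vel = np.zeros((3, 8, 4, 4, 3))
        mask = np.zeros((8, 4, 4), dtype=bool)
        fld = VelocityField(vel, np.ones((3, 8, 4, 4)), mask, 1.0, np.arange(3.0))
        with pytest.raises(ValueError, match="plane"):
            extract_mean_velocity(fld, origin=[4.0, 2.0, 2.0], normal=[1.0, 0, 0])


class TestRoundTrip:
    def test_extracted_curves_match_rasterized_input(self, tube_field):
        """Rasterize -> extract reproduces the input curves within 5% RMS."""
        fld, pts, acq, truth = tube_field
        planes = place_planes(Centerline(pts), 25)
        extracted = extract_all_planes(fld, planes)
        peak = max(c.velocities.max() for c in acq)
        for cin, cout in zip(acq, extracted):
            rms = np.sqrt(np.mean((cin.velocities - cout.velocities) ** 2))
            assert rms < 0.05 * peak

    def test_peak_time_preserved_at_plane_stations(self, tube_field):
        fld, pts, acq, _ = tube_field
        planes = place_planes(Centerline(pts), 25)
        extracted = extract_all_planes(fld, planes)
        for cin, cout in zip(acq[::6], extracted[::6]):
            t_in = cin.times[np.argmax(cin.velocities)]
            t_out = cout.times[np.argmax(cout.velocities)]
            assert abs(t_in - t_out) <= cin.dt

    def test_zero_curves_give_zero_lumen(self):
        pts = np.column_stack([np.linspace(0, 60, 61), np.zeros(61), np.zeros(61)])
        t = np.arange(0.0, 1000.0, 50.0)
        from aopwv import VelocityCurve

        curves = [
            VelocityCurve(times=t, velocities=np.zeros(t.size), plane_index=i,
                          distance_mm=d)
            for i, d in enumerate([0.0, 30.0, 60.0])
        ]
        fld = rasterize_field(curves, pts, tube_radius_mm=5.0, voxel_size_mm=2.0)
        assert np.abs(fld.velocity).max() == 0.0

    def test_thin_tube_rejected(self):
        pts = np.column_stack([np.linspace(0, 60, 61), np.zeros(61), np.zeros(61)])
        from aopwv import VelocityCurve

        t = np.arange(0.0, 1000.0, 50.0)
        curves = [
            VelocityCurve(times=t, velocities=np.zeros(t.size), distance_mm=0.0)
        ]
        with pytest.raises(ValueError, match="radius"):
            rasterize_field(curves, pts, tube_radius_mm=3.0, voxel_size_mm=2.0)


def test_npz_roundtrip(tmp_path, tube_field):
    fld, *_ = tube_field
    p = tmp_path / "field.npz"
    fld.save_npz(p)
    loaded = VelocityField.load_npz(p)
    np.testing.assert_array_equal(loaded.velocity, fld.velocity)
    np.testing.assert_array_equal(loaded.mask, fld.mask)
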