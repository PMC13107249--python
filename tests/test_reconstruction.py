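"""Centerline smoothing, rotation-minimizing frames, lofting, and areas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airwayflow.reconstruction import (
    Centerline,
    compare_states,
    cross_sectional_area,
    frames_along_centerline,
    loft_rings,
    loft_surface,
    rotation_minimizing_frames,
    smooth_centerline,
)
from airwayflow.segmentation import LumenContour


def _circle_ring(r, n=128):
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _straight_centerline(length, spacing=0.5):
    n = int(length / spacing) + 1
    z = np.arange(n) * spacing
    pts = np.column_stack([np.zeros(n), np.zeros(n), z])
    return frames_along_centerline(Centerline(points=pts, arc_length=z))


class TestSmoothCenterline:
    def test_noiseless_straight_line(self):
        z = np.linspace(0, 50, 60)
        samples = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        cl = smooth_centerline(samples, spacing=0.5)
        assert cl.residual_rms < 1e-9
        cl = frames_along_centerline(cl)
        assert np.allclose(cl.tangent, cl.tangent[0], atol=1e-9)
        assert np.allclose(np.diff(cl.arc_length), 0.5, atol=1e-9)

    def test_noiseless_planar_arc(self):
        R = 50.0
        phi = np.linspace(0, 1.5, 120)
        samples = np.column_stack([R * np.cos(phi), R * np.sin(phi), np.zeros_like(phi)])
        cl = smooth_centerline(samples, spacing=0.5)
        r = np.hypot(cl.points[:, 0], cl.points[:, 1])
        assert np.abs(r - R).max() < 0.05

    def test_noisy_line_residual_matches_noise(self):
        rng = np.random.default_rng(0)
        z = np.linspace(0, 100, 200)
        samples = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        noisy = samples + rng.normal(0, 0.5, samples.shape)
        cl = smooth_centerline(noisy, spacing=0.5, smooth_mm=0.5)
        assert cl.residual_rms == pytest.approx(0.5 * np.sqrt(3), rel=0.35)
        # reconstructed line close to truth (RMS deviation well below the noise)
        d = np.hypot(cl.points[:, 0], cl.points[:, 1])
        assert np.sqrt((d**2).mean()) < 0.2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4"):
            smooth_centerline(np.zeros((3, 3)))


class TestRotationMinimizingFrames:
    def test_straight_line_constant_frames(self):
        cl = _straight_centerline(20)
        assert np.allclose(cl.normal1, cl.normal1[0], atol=1e-12)
        assert np.allclose(cl.normal2, cl.normal2[0], atol=1e-12)

    def test_orthonormality(self):
        phi = np.linspace(0, 2.0, 200)
        pts = np.column_stack([40 * np.cos(phi), 40 * np.sin(phi), 8 * phi])
        t, n1, n2 = rotation_minimizing_frames(pts)
        assert np.abs(np.einsum("ij,ij->i", t, n1)).max() < 1e-10
        assert np.abs(np.einsum("ij,ij->i", t, n2)).max() < 1e-10
        assert np.abs(np.linalg.norm(n1, axis=1) - 1).max() < 1e-12

    def test_planar_arc_no_twist(self):
        """On a planar curve the out-of-plane normal stays fixed: < 1 deg/100 mm."""
        R = 60.0
        phi = np.linspace(0, 2.0, 400)  # 120 mm arc
        pts = np.column_stack([R * np.cos(phi), np.zeros_like(phi), R * np.sin(phi)])
        _, n1, n2 = rotation_minimizing_frames(pts)
        # +y is normal to the curve plane; one of the frame normals tracks it
        ny = np.abs(n2 @ np.array([0.0, 1.0, 0.0]))
        twist_deg = np.degrees(np.arccos(np.clip(ny, -1, 1)))
        arc = R * 2.0
        assert twist_deg.max() <= 1.0 * arc / 100.0

    def test_zero_length_tangent_rejected(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [0, 0, 1], [0, 0, 2.0]])
        with pytest.raises(ValueError, match="tangent"):
            rotation_minimizing_frames(pts)


def _contours_from_rings(rings, spacing=0.5):
    out = []
    for i, ring in enumerate(rings):
        out.append(
            LumenContour(
                frame_index=i,
                z_mm=i * spacing,
                vertices=ring,
                valid=np.ones(len(ring), bool),
            )
        )
    return out


class TestLoft:
    def test_cylinder_volume(self):
        cl = _straight_centerline(10)
        contours = _contours_from_rings([_circle_ring(6.0)] * cl.n_stations)
        surf = loft_surface(contours, cl, trim=(0, 0), vertices_per_station=128)
        assert surf.is_watertight
        assert surf.volume == pytest.approx(np.pi * 36 * 10, rel=0.01)

    def test_trim_removes_end_volume(self):
        cl = _straight_centerline(10)
        contours = _contours_from_rings([_circle_ring(6.0)] * cl.n_stations)
        surf = loft_surface(contours, cl, trim=(2, 2), vertices_per_station=128)
        assert surf.volume == pytest.approx(np.pi * 36 * 6, rel=0.01)

    def test_aligned_rings_need_no_roll(self):
        cl = _straight_centerline(5)
        surf = loft_rings([_circle_ring(4.0)] * cl.n_stations, cl)
        assert np.all(surf.roll_offsets == 0)

    def test_rigid_placement_preserves_area(self):
        """3D ring area after placement equals the 2D polygon area to 1e-9."""
        phi = np.linspace(0, 1.2, 40)
        pts = np.column_stack([30 * np.cos(phi), 30 * np.sin(phi), 12 * phi])
        arc = np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        cl = frames_along_centerline(Centerline(points=pts, arc_length=arc))
        ring = _circle_ring(3.0, 64) * np.array([1.0, 0.7])  # ellipse
        surf = loft_rings([ring] * cl.n_stations, cl, roll_register=False)
        a2d = cross_sectional_area(ring)
        for i in (0, len(pts) // 2, len(pts) - 1):
            sel = surf.station_of_vertex == i
            world = surf.vertices[sel]
            # planar polygon area via the cross-product sum
            c = world.mean(axis=0)
            v = world - c
            cross = np.cross(v, np.roll(v, -1, axis=0))
            a3d = 0.5 * np.linalg.norm(cross.sum(axis=0))
            assert a3d == pytest.approx(a2d, rel=1e-9)

    def test_vertex_count_mismatch_rejected(self):
        cl = _straight_centerline(2)
        rings = [_circle_ring(4.0, 128)] * (cl.n_stations - 1) + [_circle_ring(4.0, 64)]
        with pytest.raises(ValueError, match="vertex count"):
            loft_rings(rings, cl)

    def test_extension_adds_straight_tube_volume(self):
        cl = _straight_centerline(10)
        contours = _contours_from_rings([_circle_ring(6.0)] * cl.n_stations)
        surf = loft_surface(
            contours, cl, trim=(0, 0), vertices_per_station=128, extension_mm=5.0
        )
        assert surf.is_watertight
        assert surf.volume == pytest.approx(np.pi * 36 * 20, rel=0.01)


class TestCrossSectionalArea:
    def test_unit_square_exact(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        assert cross_sectional_area(sq) == 1.0

    def test_regular_2000gon_approximates_circle(self):
        assert cross_sectional_area(_circle_ring(1.0, 2000)) == pytest.approx(
            np.pi, abs=1e-4
        )

    def test_orientation_independent(self):
        ring = _circle_ring(2.0, 64)
        assert cross_sectional_area(ring[::-1]) == pytest.approx(
            cross_sectional_area(ring), rel=1e-12
        )

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1.0]])
        with pytest.raises(ValueError, match="self-intersect"):
            cross_sectional_area(bowtie)


class TestCompareStates:
    def test_known_reduction(self):
        z = np.linspace(0, 10, 21)
        red = compare_states(
            z, np.full_like(z, 100.0), z, np.full_like(z, 44.0), {"r": (2.0, 8.0)}
        )
        assert red["r"] == pytest.approx(56.0)

    def test_identical_profiles_zero(self):
        z = np.linspace(0, 10, 21)
        a = 100 + 5 * np.sin(z)
        red = compare_states(z, a, z, a.copy(), {"r": (1.0, 9.0)})
        assert red["r"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_window_rejected(self):
        z = np.linspace(0, 10, 21)
        with pytest.raises(ValueError, match="no stations"):
            compare_states(z, z + 1, z, z + 1, {"r": (20.0, 30.0)})

    @settings(deadline=None, max_examples=25)
    @given(
        ma=st.floats(10.0, 200.0),
        mb=st.floats(10.0, 200.0),
    )
    def test_antisymmetry_identity(self, ma, mb):
        """reduction(a,b) and reduction(b,a) satisfy the mean-ratio identity."""
        z = np.linspace(0, 10, 11)
        a, b = np.full_like(z, ma), np.full_like(z, mb)
        w = {"r": (0.0, 10.0)}
        r_ab = compare_states(z, a, z, b, w)["r"]
        r_ba = compare_states(z, b, z, a, w)["r"]
        assert r_ab == pytest.approx(100.0 - 100.0**2 / (100.0 - r_ba), rel=1e-9)
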