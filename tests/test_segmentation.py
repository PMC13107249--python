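"""Wall detection, contour assembly, and missing-sector filling."""

import numpy as np
import pytest

from airwayflow.imaging import mask_sheath_artifact
from airwayflow.phantom import RenderParams, render_bscan
from airwayflow.reconstruction import cross_sectional_area
from airwayflow.segmentation import (
    LumenContour,
    NoiseStats,
    SegmentationParams,
    contour_from_frame,
    detect_wall,
    detect_walls,
    fill_missing_sectors,
)
from conftest import straight_phantom

STATS = NoiseStats(mean=0.04, sd=0.008)


class TestDetectWall:
    def test_clean_echo_found_at_depth(self):
        pitch = 12.8 / 512
        a_line = np.zeros(512)
        j = int(4.0 / pitch)
        a_line[j : j + 20] = 1.0
        d = detect_wall(a_line, STATS, 1.2, pitch)
        assert d == pytest.approx(4.0, abs=pitch)

    def test_all_noise_returns_missing(self):
        rng = np.random.default_rng(0)
        a_line = np.abs(rng.normal(0.04, 0.008, 512))
        assert detect_wall(a_line, STATS, 1.2, 12.8 / 512) is None

    def test_echo_inside_exclusion_ignored(self):
        pitch = 12.8 / 512
        a_line = np.zeros(512)
        a_line[10:30] = 1.0  # sheath-range echo
        assert detect_wall(a_line, STATS, 1.2, pitch) is None

    def test_phantom_frame_depths_match_geometry(self, small_geometry):
        """Detected depths within one pixel of analytic radii for >=99% of angles."""
        ph = straight_phantom(radius=4.0, offset=(0.8, 0.4), seed=2)
        frame = render_bscan(ph, small_geometry, 10.0, params=RenderParams(sheath=False))
        stats = NoiseStats.from_frame(frame)
        depths, found = detect_walls(
            frame.intensity.astype(float), stats, 1.2, frame.pixel_pitch
        )
        truth = ph.wall_distance(10.0, frame.angles)
        ok = found & (np.abs(depths - truth) <= frame.pixel_pitch)
        assert ok.mean() >= 0.99


class TestContourFromFrame:
    def test_centered_circle_radii(self, centered_frame):
        c = contour_from_frame(centered_frame)
        assert c.usable and c.valid.all()
        assert np.abs(c.radii - 4.0).max() <= centered_frame.pixel_pitch

    def test_eccentric_centroid_recovers_offset(self, small_geometry):
        ph = straight_phantom(radius=4.0, offset=(1.0, 0.5), seed=4)
        s = 10.0
        frame = render_bscan(ph, small_geometry, s, params=RenderParams(sheath=False))
        c = contour_from_frame(frame)
        offset = ph.catheter_offset(s)[0]
        assert np.allclose(c.centroid(), -offset, atol=0.05)
        assert c.radii.min() > 4.0 - np.hypot(*offset) - 0.1
        assert c.radii.max() < 4.0 + np.hypot(*offset) + 0.1

    def test_missing_sector_flags_propagate(self, centered_frame):
        import dataclasses

        n = centered_frame.n_angles
        valid = np.ones(n, bool)
        sector = slice(0, int(n * 40 / 360))
        valid[sector] = False
        frame = dataclasses.replace(
            centered_frame,
            intensity=centered_frame.intensity.copy(),
            sector_valid=valid,
        )
        c = contour_from_frame(frame)
        assert not c.valid[sector].any()
        good = c.valid
        assert np.abs(c.radii[good] - 4.0).max() <= frame.pixel_pitch

    def test_mostly_missing_frame_flagged_unusable(self, centered_frame):
        import dataclasses

        valid = np.zeros(centered_frame.n_angles, bool)
        valid[: centered_frame.n_angles // 4] = True
        frame = dataclasses.replace(
            centered_frame,
            intensity=centered_frame.intensity.copy(),
            sector_valid=valid,
        )
        assert not contour_from_frame(frame).usable

    def test_area_invariant_under_vertex_rotation(self, centered_frame):
        c = contour_from_frame(centered_frame)
        a0 = cross_sectional_area(c)
        rolled = np.roll(c.vertices, 57, axis=0)
        assert cross_sectional_area(rolled) == pytest.approx(a0, rel=1e-12)

    def test_end_to_end_area_within_two_percent(self, small_geometry):
        ph = straight_phantom(radius=4.0, offset=(0.6, 0.2), seed=6)
        frame = render_bscan(ph, small_geometry, 10.0)
        frame = mask_sheath_artifact(frame, (0.7, 1.1))
        c = contour_from_frame(frame)
        truth = float(ph.true_area(10.0)[0])
        assert cross_sectional_area(c) == pytest.approx(truth, rel=0.02)


def _ring_contour(frame_index, radius, n=64, invalid=()):
    theta = 2 * np.pi * np.arange(n) / n
    valid = np.ones(n, bool)
    valid[list(invalid)] = False
    r = np.full(n, float(radius))
    r[~valid] = np.nan
    return LumenContour(
        frame_index=frame_index,
        z_mm=0.5 * frame_index,
        vertices=np.column_stack([r * np.cos(theta), r * np.sin(theta)]),
        valid=valid,
    )


class TestFillMissingSectors:
    def test_flat_interpolation_across_frames(self):
        contours = [
            _ring_contour(9, 5.0),
            _ring_contour(10, 5.0, invalid=[3]),
            _ring_contour(11, 5.0),
        ]
        filled = fill_missing_sectors(contours)
        assert filled[1].radii[3] == pytest.approx(5.0)
        assert not filled[1].valid[3]  # stays flagged extrapolated

    def test_midpoint_interpolation(self):
        contours = [
            _ring_contour(9, 4.0),
            _ring_contour(10, 4.0, invalid=[3]),
            _ring_contour(11, 6.0),
        ]
        contours[1].vertices[5] = [
            5.0 * np.cos(2 * np.pi * 5 / 64),
            5.0 * np.sin(2 * np.pi * 5 / 64),
        ]
        filled = fill_missing_sectors(contours)
        assert filled[1].radii[3] == pytest.approx(5.0)

    def test_valid_vertices_never_modified(self):
        contours = [
            _ring_contour(0, 4.0),
            _ring_contour(1, 5.0, invalid=[0, 1, 2]),
            _ring_contour(2, 6.0),
        ]
        before = [c.vertices.copy() for c in contours]
        filled = fill_missing_sectors(contours)
        for c, b, f in zip(contours, before, filled):
            assert np.array_equal(f.vertices[c.valid], b[c.valid])

    def test_angular_fallback_within_frame(self):
        # single frame: no neighbors; angular interpolation fills the gap
        contours = [_ring_contour(0, 5.0, invalid=[10, 11])]
        filled = fill_missing_sectors(contours)
        assert filled[0].radii[10] == pytest.approx(5.0, rel=1e-6)

    def test_fully_missing_contour_raises_with_indices(self):
        contours = [_ring_contour(0, 5.0, invalid=range(64))]
        with pytest.raises(ValueError, match="frame indices \\[0\\]"):
            fill_missing_sectors(contours)

    def test_range_clipped_phantom_areas_recovered(self, small_geometry):
        """Sectors beyond the 12.8 mm range are filled to within 3% of truth."""
        from airwayflow.segmentation import contour_from_frame

        ph = straight_phantom(radius=11.5, offset=(1.6, 0.0), span=20.0, seed=8)
        frames = [
            render_bscan(ph, small_geometry, z, params=RenderParams(sheath=False))
            for z in (9.5, 10.0, 10.5)
        ]
        assert not all(f.sector_valid.all() for f in frames)
        contours = [contour_from_frame(f) for f in frames]
        filled = fill_missing_sectors(contours)
        for z, c in zip((9.5, 10.0, 10.5), filled):
            truth = float(ph.true_area(z)[0])
            assert cross_sectional_area(c) == pytest.approx(truth, rel=0.03)
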