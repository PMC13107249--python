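"""Automated lumen-wall detection producing closed contours per B-scan.

Replaces a manual contouring workflow: each A-line is scanned outward from an
exclusion zone around the catheter/sheath for the first sustained
threshold crossing (the near edge of the wall echo), the per-angle wall
ranges become a closed polygon in catheter-centered coordinates, and sectors
whose wall fell outside the imaging range are filled from neighboring frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import PolarBScan, estimate_noise_floor

__all__ = [
    "NoiseStats",
    "SegmentationParams",
    "LumenContour",
    "detect_wall",
    "detect_walls",
    "contour_from_frame",
    "fill_missing_sectors",
]


@dataclass
class NoiseStats:
    """Additive noise-floor statistics used to set the detection threshold."""

    mean: float
    sd: float

    @classmethod
    def from_frame(cls, frame: PolarBScan) -> "NoiseStats":
        mean, sd = estimate_noise_floor(frame)
        return cls(mean, sd)


@dataclass
class SegmentationParams:
    """Wall-detector tuning.

    ``k_sigma`` and ``min_run`` define the first-crossing rule: the wall is
    the first run of at least ``min_run`` consecutive depth samples exceeding
    ``noise_mean + k_sigma * noise_sd`` beyond the ``exclusion_mm`` zone.
    """

    exclusion_mm: float = 1.2
    k_sigma: float = 4.0
    min_run: int = 5
    smooth_window: int = 9          # circular moving-average window (vertices)
    max_missing_fraction: float = 0.5


@dataclass
class LumenContour:
    """Closed lumen-wall polygon at one pullback station.

    Vertices are ordered by strictly increasing beam angle in the
    catheter-centered frame; ``valid[i]`` is False where the wall was not
    observed (out of range) and the vertex was or will be extrapolated.
    """

    frame_index: int
    z_mm: float
    vertices: np.ndarray                 # (n, 2) mm
    valid: np.ndarray                    # (n,) bool; False = extrapolated
    usable: bool = True
    closed: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.valid = np.asarray(self.valid, bool)
        if len(self.vertices) < 64:
            raise ValueError("a lumen contour needs at least 64 vertices")
        if self.vertices.shape != (len(self.valid), 2):
            raise ValueError("vertices must be (n, 2) with one flag per vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_vertices) / self.n_vertices

    @property
    def radii(self) -> np.ndarray:
        return np.hypot(self.vertices[:, 0], self.vertices[:, 1])

    @property
    def extrapolated_fraction(self) -> float:
        return float(1.0 - self.valid.mean())

    def centroid(self) -> np.ndarray:
        """Area centroid of the polygon (mm, catheter-centered)."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = cross.sum() / 2.0
        cx = ((x + xn) * cross).sum() / (6.0 * a)
        cy = ((y + yn) * cross).sum() / (6.0 * a)
        return np.array([cx, cy])


def detect_wall(
    a_line: np.ndarray,
    noise_stats: NoiseStats,
    exclusion_mm: float,
    pixel_pitch: float,
    k_sigma: float = 4.0,
    min_run: int = 5,
) -> float | None:
    """Depth (mm) of the lumen wall on one A-line, or None if not found.

    The wall is the start of the first run of at least ``min_run`` consecutive
    samples above ``mean + k_sigma * sd`` beyond the exclusion zone.
    """
    depths, found = detect_walls(
        np.asarray(a_line, float)[None, :],
        noise_stats,
        exclusion_mm,
        pixel_pitch,
        k_sigma=k_sigma,
        min_run=min_run,
    )
    return float(depths[0]) if found[0] else None


def detect_walls(
    intensity: np.ndarray,
    noise_stats: NoiseStats,
    exclusion_mm: float,
    pixel_pitch: float,
    k_sigma: float = 4.0,
    min_run: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized first-crossing wall detection over all A-lines of a frame."""
    depth_pixels = intensity.shape[1]
    if exclusion_mm >= depth_pixels * pixel_pitch:
        raise ValueError("exclusion zone covers the whole depth range")
    j0 = int(np.ceil(exclusion_mm / pixel_pitch))
    thr = noise_stats.mean + k_sigma * noise_stats.sd
    above = intensity[:, j0:] > thr
    if above.shape[1] < min_run:
        return np.full(intensity.shape[0], np.nan), np.zeros(intensity.shape[0], bool)
    windows = np.lib.stride_tricks.sliding_window_view(above, min_run, axis=1)
    runs = windows.all(axis=2)
    found = runs.any(axis=1)
    idx = np.argmax(runs, axis=1) + j0
    depths = (idx + 0.5) * pixel_pitch
    depths[~found] = np.nan
    return depths, found


def _circular_masked_smooth(radii: np.ndarray, valid: np.ndarray, window: int) -> np.ndarray:
    """Periodic moving average that ignores (and never overwrites) invalid vertices."""
    if window <= 1:
        return radii.copy()
    kernel = np.ones(window)
    v = valid.astype(float)
    rv = np.where(valid, radii, 0.0)
    num = np.convolve(np.concatenate([rv, rv, rv]), kernel, mode="same")[len(rv): 2 * len(rv)]
    den = np.convolve(np.concatenate([v, v, v]), kernel, mode="same")[len(v): 2 * len(v)]
    out = radii.copy()
    ok = valid & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def contour_from_frame(
    frame: PolarBScan,
    params: SegmentationParams | None = None,
    noise_stats: NoiseStats | None = None,
) -> LumenContour:
    """Detect the lumen wall on every A-line and assemble a closed contour.

    Sectors with no detected wall (or flagged truth-missing upstream) are
    marked invalid; a periodic moving average over the valid vertices smooths
    speckle-induced jitter.  A contour with more than
    ``max_missing_fraction`` invalid sectors is flagged unusable.
    """
    params = params or SegmentationParams()
    noise_stats = noise_stats or NoiseStats.from_frame(frame)
    depths, found = detect_walls(
        frame.intensity.astype(float),
        noise_stats,
        params.exclusion_mm,
        frame.pixel_pitch,
        k_sigma=params.k_sigma,
        min_run=params.min_run,
    )
    valid = found & frame.sector_valid
    radii = _circular_masked_smooth(depths, valid, params.smooth_window)
    radii = np.where(valid, radii, np.nan)
    theta = 2.0 * np.pi * np.arange(frame.n_angles) / frame.n_angles
    vertices = np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
    usable = (1.0 - valid.mean()) <= params.max_missing_fraction
    return LumenContour(
        frame_index=frame.frame_index,
        z_mm=frame.z_nominal,
        vertices=vertices,
        valid=valid,
        usable=usable,
    )


def fill_missing_sectors(
    contours: list[LumenContour], max_gap_frames: int = 10
) -> list[LumenContour]:
    """Fill invalid sectors from neighboring frames, then within the frame.

    For every beam angle, invalid radii are linearly interpolated in frame
    index between the nearest valid same-angle neighbors, searching at most
    ``max_gap_frames`` frames away on each side.  Radii still missing after
    that are filled by periodic angular interpolation within their own frame.
    Filled vertices remain flagged as extrapolated (``valid`` stays False);
    valid vertices are never modified.
    """
    if not contours:
        return []
    n = contours[0].n_vertices
    if any(c.n_vertices != n for c in contours):
        raise ValueError("all contours must share the same angular grid")
    radii = np.vstack([c.radii for c in contours])          # (n_frames, n_angles)
    valid = np.vstack([c.valid for c in contours])
    filled = radii.copy()

    frames = np.arange(len(contours))
    for a in range(n):
        col_valid = valid[:, a]
        if col_valid.all():
            continue
        if col_valid.any():
            good = frames[col_valid]
            interp = np.interp(frames, good, radii[col_valid, a])
            # distance to nearest valid frame on each side
            prev_idx = np.searchsorted(good, frames, side="right") - 1
            next_idx = np.clip(prev_idx + 1, 0, len(good) - 1)
            prev_idx = np.clip(prev_idx, 0, len(good) - 1)
            dist = np.minimum(np.abs(frames - good[prev_idx]), np.abs(good[next_idx] - frames))
            ok = (~col_valid) & (dist <= max_gap_frames)
            filled[ok, a] = interp[ok]
            still = (~col_valid) & ~ok
        else:
            still = ~col_valid
        filled[still, a] = np.nan

    # angular interpolation within each frame for what remains
    hopeless: list[int] = []
    theta = 2.0 * np.pi * np.arange(n) / n
    for i in range(len(contours)):
        row = filled[i]
        miss = np.isnan(row)
        if not miss.any():
            continue
        if miss.all():
            hopeless.append(contours[i].frame_index)
            continue
        good = np.where(~miss)[0]
        # periodic interpolation: extend the angle axis by one wrap
        th_ext = np.concatenate([theta[good], theta[good[:1]] + 2 * np.pi])
        r_ext = np.concatenate([row[good], row[good[:1]]])
        th_miss = np.where(theta[miss] < theta[good[0]], theta[miss] + 2 * np.pi, theta[miss])
        filled[i, miss] = np.interp(th_miss, th_ext, r_ext)
    if hopeless:
        raise ValueError(
            f"contours fully missing beyond the +/-{max_gap_frames}-frame "
            f"search limit at frame indices {hopeless}"
        )

    out = []
    for i, c in enumerate(contours):
        verts = np.column_stack(
            [filled[i] * np.cos(theta), filled[i] * np.sin(theta)]
        )
        # exact preservation of valid vertices
        verts[c.valid] = c.vertices[c.valid]
        out.append(
            LumenContour(
                frame_index=c.frame_index,
                z_mm=c.z_mm,
                vertices=verts,
                valid=c.valid.copy(),
                usable=c.usable,
            )
        )
    return out
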