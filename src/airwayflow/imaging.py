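"""Polar B-scan containers and the raw-image post-processing chain.

A rotational endoscopic OCT frame is acquired natively in polar coordinates:
one axial depth profile (A-line) per catheter angle.  This module holds the
:class:`PolarBScan` container and the preprocessing steps applied before
segmentation: polar <-> Cartesian resampling, suppression of the specular
sheath-reflection ring artifact, optional decimation, and sequential
rotational alignment of a pullback stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter1d

__all__ = [
    "PolarBScan",
    "polar_to_cartesian",
    "cartesian_to_polar",
    "mask_sheath_artifact",
    "wall_signature",
    "align_frames",
    "decimate",
]


@dataclass
class PolarBScan:
    """One rotational OCT frame: intensity indexed by (angle, depth).

    A-line ``k`` points along ``theta = 2*pi*k / n_angles`` (counter-clockwise
    from +x).  Depth pixel ``j`` is centered at ``(j + 0.5) * pixel_pitch``
    millimetres from the catheter axis.  ``sector_valid[k]`` is False where the
    wall lies beyond the imaging range so no echo was recorded.
    """

    intensity: np.ndarray          # (n_angles, depth_pixels), non-negative
    pixel_pitch: float             # mm per depth pixel
    frame_index: int
    z_nominal: float               # mm along the pullback, frame_index * spacing
    sector_valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2D (angles x depth)")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if self.sector_valid is None:
            self.sector_valid = np.ones(self.n_angles, dtype=bool)
        self.sector_valid = np.asarray(self.sector_valid, dtype=bool)
        if self.sector_valid.shape != (self.n_angles,):
            raise ValueError("sector_valid must have one flag per A-line")

    @property
    def n_angles(self) -> int:
        return self.intensity.shape[0]

    @property
    def depth_pixels(self) -> int:
        return self.intensity.shape[1]

    @property
    def depth_range(self) -> float:
        """Maximum imaged depth in mm."""
        return self.pixel_pitch * self.depth_pixels

    @property
    def angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_angles) / self.n_angles

    @property
    def depths(self) -> np.ndarray:
        """Depth-pixel center coordinates in mm."""
        return (np.arange(self.depth_pixels) + 0.5) * self.pixel_pitch


def polar_to_cartesian(
    frame: PolarBScan, out_pixel_mm: float, order: int = 1
) -> np.ndarray:
    """Resample a polar frame onto a square Cartesian grid.

    The grid is centered on the catheter axis; a polar sample at angle theta
    and depth d lands at ``(d cos(theta), d sin(theta))``.  Returns an image of
    shape (n, n) with ``n = 2 * ceil(depth_range / out_pixel_mm) + 1`` so the
    axis pixel sits exactly at the center.
    """
    if out_pixel_mm <= 0:
        raise ValueError("out_pixel_mm must be positive")
    half = int(np.ceil(frame.depth_range / out_pixel_mm))
    coords = (np.arange(2 * half + 1) - half) * out_pixel_mm
    x, y = np.meshgrid(coords, coords, indexing="ij")
    r = np.hypot(x, y)
    theta = np.mod(np.arctan2(y, x), 2.0 * np.pi)
    # fractional indices into the (angle, depth) grid
    ia = theta / (2.0 * np.pi) * frame.n_angles
    ir = r / frame.pixel_pitch - 0.5
    out = map_coordinates(
        frame.intensity.astype(float),
        [ia, ir],
        order=order,
        mode="grid-wrap",
        cval=0.0,
    )
    # grid-wrap also wraps depth; zero out-of-range radii explicitly
    out[ir > frame.depth_pixels - 1] = 0.0
    out[out < 0] = 0.0
    return out


def cartesian_to_polar(
    image: np.ndarray,
    in_pixel_mm: float,
    n_angles: int,
    depth_pixels: int,
    pixel_pitch: float,
    frame_index: int = 0,
    z_nominal: float = 0.0,
    order: int = 1,
) -> PolarBScan:
    """Inverse of :func:`polar_to_cartesian` (to within interpolation error)."""
    if in_pixel_mm <= 0 or pixel_pitch <= 0:
        raise ValueError("pixel pitches must be positive")
    image = np.asarray(image, dtype=float)
    cx = (image.shape[0] - 1) / 2.0
    cy = (image.shape[1] - 1) / 2.0
    theta = 2.0 * np.pi * np.arange(n_angles) / n_angles
    d = (np.arange(depth_pixels) + 0.5) * pixel_pitch
    xx = d[None, :] * np.cos(theta)[:, None] / in_pixel_mm + cx
    yy = d[None, :] * np.sin(theta)[:, None] / in_pixel_mm + cy
    out = map_coordinates(image, [xx, yy], order=order, mode="constant", cval=0.0)
    out[out < 0] = 0.0
    return PolarBScan(out, pixel_pitch, frame_index, z_nominal)


def estimate_noise_floor(
    frame: PolarBScan, window_mm: tuple[float, float] = (1.2, 2.2)
) -> tuple[float, float]:
    """Estimate the additive noise floor (median, robust sd) of a frame.

    The clear lumen between the sheath and the airway wall carries no
    backscatter, so the depth window just beyond the sheath exclusion zone is
    signal-free for any lumen wider than ``window_mm[1]``.  The spread uses
    the median absolute deviation so stray bright pixels do not inflate it.
    """
    lo = int(window_mm[0] / frame.pixel_pitch)
    hi = max(lo + 1, int(window_mm[1] / frame.pixel_pitch))
    hi = min(hi, frame.depth_pixels)
    patch = frame.intensity[:, lo:hi].astype(float)
    med = float(np.median(patch))
    sd = float(1.4826 * np.median(np.abs(patch - med)))
    return med, sd


def mask_sheath_artifact(frame: PolarBScan, band: tuple[float, float]) -> PolarBScan:
    """Replace the sheath-reflection ring inside ``band`` with the noise floor.

    ``band`` is a ``(r_min, r_max)`` depth interval in mm; every pixel whose
    depth lies in the closed band is replaced by the estimated noise-floor
    mean, all other pixels are left bit-identical.
    """
    r_min, r_max = band
    if not (0 <= r_min < r_max < frame.depth_range):
        raise ValueError(
            f"band must satisfy 0 <= r_min < r_max < depth_range "
            f"({frame.depth_range} mm); got {band}"
        )
    floor, _ = estimate_noise_floor(frame)
    sel = (frame.depths >= r_min) & (frame.depths <= r_max)
    out = frame.intensity.copy()
    out[:, sel] = floor
    return replace(frame, intensity=out, sector_valid=frame.sector_valid.copy())


def wall_signature(frame: PolarBScan, exclusion_mm: float = 1.2) -> np.ndarray:
    """Per-angle intensity-weighted mean depth (mm) beyond an exclusion zone.

    Used as a cheap rotation-registration feature: the center of mass of each
    A-line averages speckle over hundreds of pixels, so the signature varies
    smoothly with angle and rotates rigidly with the anatomy.
    """
    j0 = int(np.ceil(exclusion_mm / frame.pixel_pitch))
    inten = frame.intensity[:, j0:].astype(float)
    mean, sd = estimate_noise_floor(frame)
    above = inten > mean + 4.0 * sd
    run = 3
    windows = np.lib.stride_tricks.sliding_window_view(above, run, axis=1)
    hits = windows.all(axis=2)
    found = hits.any(axis=1)
    idx = np.argmax(hits, axis=1).astype(float) + j0
    if found.any():
        idx[~found] = np.median(idx[found])
    depth = (idx + 0.5) * frame.pixel_pitch
    return uniform_filter1d(depth, size=max(frame.n_angles // 128, 3), mode="wrap")


def _circular_shift_estimate(sig_a: np.ndarray, sig_b: np.ndarray) -> int:
    """Cyclic shift (in A-lines) that best maps ``sig_b`` onto ``sig_a``.

    Maximizes the circular cross-correlation of the mean-subtracted
    signatures; returns a signed shift in ``[-n/2, n/2)``.
    """
    a = sig_a - sig_a.mean()
    b = sig_b - sig_b.mean()
    corr = np.fft.irfft(np.fft.rfft(a) * np.conj(np.fft.rfft(b)), n=a.size)
    shift = int(np.argmax(corr))
    if shift >= a.size // 2:
        shift -= a.size
    return shift


def align_frames(
    stack: list[PolarBScan], exclusion_mm: float = 1.2
) -> tuple[list[PolarBScan], np.ndarray]:
    """Rotationally register each frame of a pullback stack to its predecessor.

    The per-angle wall-distance signature of each frame is circularly
    cross-correlated with the previous frame's signature; the cumulative
    rotation is applied with ``np.roll``.  Returns the aligned stack and the
    per-frame cumulative offsets in A-lines (first frame is the reference,
    offset 0).
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    offsets = np.zeros(len(stack), dtype=int)
    if len(stack) == 1:
        return list(stack), offsets
    aligned = [stack[0]]
    prev_sig = wall_signature(stack[0], exclusion_mm)
    cum = 0
    for i, frame in enumerate(stack[1:], start=1):
        sig = wall_signature(frame, exclusion_mm)
        cum += _circular_shift_estimate(prev_sig, np.roll(sig, cum))
        offsets[i] = cum
        aligned.append(
            replace(
                frame,
                intensity=np.roll(frame.intensity, cum, axis=0),
                sector_valid=np.roll(frame.sector_valid, cum),
            )
        )
        prev_sig = wall_signature(aligned[-1], exclusion_mm)
    return aligned, offsets


def decimate(frame: PolarBScan, angle_factor: int = 1, depth_factor: int = 1) -> PolarBScan:
    """Integer decimation in angle and/or depth (block averaging in depth)."""
    if angle_factor < 1 or depth_factor < 1:
        raise ValueError("decimation factors must be >= 1")
    inten = frame.intensity[::angle_factor]
    valid = frame.sector_valid[::angle_factor]
    if depth_factor > 1:
        n = (inten.shape[1] // depth_factor) * depth_factor
        inten = inten[:, :n].reshape(inten.shape[0], -1, depth_factor).mean(axis=2)
    return PolarBScan(
        inten,
        frame.pixel_pitch * depth_factor,
        frame.frame_index,
        frame.z_nominal,
        valid,
    )
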