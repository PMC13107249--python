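"""Synthetic upper-airway phantoms and rotational OCT pullback rendering.

The phantom stands in for the patient: a curved pharyngeal tube whose
cross-sections are circles (optionally ellipses) with a known radius profile,
named anatomical region windows along the arc length, and a per-region area
constriction that distinguishes the asleep from the awake state.  From a
phantom this module renders what the catheter would record during a motorized
pullback — polar B-scans with speckle, a noise floor, and the bright
sheath-reflection ring — plus the electromagnetic-tracker samples of the
catheter path, and exposes analytic ground truth (areas, watertight mesh) for
every downstream stage.

Default acquisition parameters follow the long-range swept-source system the
package emulates: 25 frames/s, 2000 A-lines per frame, 12.5 mm/s pullback
(hence 0.5 mm frame spacing), 12.8 mm imaging range, 10 um axial PSF.
The asleep state constricts the nasopharynx, base-of-tongue, and epiglottic
region cross-sectional areas to 0.92, 0.44, and 0.68 of their awake values
(8%, 56%, and 32% reductions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import erf

from .imaging import PolarBScan

__all__ = [
    "AcquisitionGeometry",
    "AirwayPhantom",
    "RenderParams",
    "DEFAULT_REGION_WINDOWS",
    "SLEEP_CONSTRICTION",
    "BREATHS_PER_MINUTE",
    "make_phantom",
    "render_bscan",
    "iter_pullback",
    "tracker_samples",
    "simulate_pullback",
    "ground_truth",
]

#: Named anatomical intervals along the pullback arc length (mm).
DEFAULT_REGION_WINDOWS: dict[str, tuple[float, float]] = {
    "nasopharynx": (15.0, 40.0),
    "velopharynx": (48.0, 62.0),
    "base_of_tongue": (70.0, 95.0),
    "epiglottis": (103.0, 123.0),
    "hypopharynx": (130.0, 145.0),
}

#: Asleep-state area scale factors: 8%, 56%, and 32% reductions in the
#: nasopharynx, base of tongue, and epiglottic regions respectively.
SLEEP_CONSTRICTION: dict[str, float] = {
    "nasopharynx": 0.92,
    "base_of_tongue": 0.44,
    "epiglottis": 0.68,
}

#: Normal resting respiration rate; one breath every ~8.6 s.
BREATHS_PER_MINUTE: float = 7.0


@dataclass
class AcquisitionGeometry:
    """Scan-head and pullback timing parameters of the rotational OCT system."""

    frames_per_s: float = 25.0
    alines_per_frame: int = 2000
    pullback_speed: float = 12.5   # mm/s
    depth_range: float = 12.8      # mm
    depth_pixels: int = 1024
    axial_psf_fwhm: float = 0.010  # mm

    def __post_init__(self) -> None:
        for name in ("frames_per_s", "pullback_speed", "depth_range", "axial_psf_fwhm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alines_per_frame < 8 or self.depth_pixels < 8:
            raise ValueError("alines_per_frame and depth_pixels must be >= 8")

    @property
    def frame_spacing(self) -> float:
        """Pullback distance between consecutive B-scans (mm)."""
        return self.pullback_speed / self.frames_per_s

    @property
    def pixel_pitch(self) -> float:
        """Depth sampling pitch (mm/pixel)."""
        return self.depth_range / self.depth_pixels


@dataclass
class RenderParams:
    """Image-formation parameters of the synthetic B-scan renderer.

    Intensities are in arbitrary units normalized so the specular wall echo
    has unit amplitude before speckle.  The sheath ring models the specular
    reflection off the stationary transparent FEP sheath.
    """

    echo_amp: float = 1.0        # specular wall-echo peak amplitude
    tissue_amp: float = 0.6      # sub-surface scattering amplitude
    atten_mm: float = 1.0        # 1/e attenuation depth into tissue (mm)
    sheath_radius: float = 0.9   # mm
    sheath_amp: float = 2.0
    sheath_sigma: float = 0.02   # mm, radial width of the ring
    floor_mean: float = 0.04     # additive noise floor
    floor_sd: float = 0.008
    speckle: bool = True         # multiplicative Rayleigh speckle (mean 1)
    sheath: bool = True


def _default_control_points() -> np.ndarray:
    """Gently curved pharyngeal path: ends aligned with +z, mid-span bend."""
    z = np.linspace(0.0, 147.0, 13)
    x = 4.0 * (1.0 - np.cos(2.0 * np.pi * z / 147.0))
    y = np.zeros_like(z)
    return np.column_stack([x, y, z])


@dataclass
class AirwayPhantom:
    """Analytic airway tube with named regions and a per-state constriction.

    All axial coordinates are arc length ``s`` (mm) along the anatomical
    centerline, measured from the distal (first-imaged) end.  The catheter
    runs inside the lumen offset from the anatomical center by
    ``catheter_offset`` (expressed in the local cross-section frame).
    """

    centerline_control_points: np.ndarray = field(default_factory=_default_control_points)
    radius_stations: np.ndarray = field(default_factory=lambda: np.array([0.0, 150.0]))
    radius_values: np.ndarray = field(default_factory=lambda: np.array([6.0, 6.0]))
    region_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WINDOWS)
    )
    state_constriction: dict[str, float] = field(default_factory=dict)
    offset_amplitude: tuple[float, float] = (0.8, 0.5)  # mm, catheter eccentricity
    ellipticity: float = 1.0       # a/b axis ratio of the cross-section ellipse
    taper_mm: float = 3.0          # cosine transition width outside window edges
    acquisition_span: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.centerline_control_points = np.asarray(self.centerline_control_points, float)
        self.radius_stations = np.asarray(self.radius_stations, float)
        self.radius_values = np.asarray(self.radius_values, float)
        if np.any(self.radius_values <= 0):
            raise ValueError("all radii must be strictly positive")
        for name, fac in self.state_constriction.items():
            if not (0.0 < fac <= 1.0):
                raise ValueError(f"area scale factor for {name!r} must be in (0, 1]")
        windows = sorted(self.region_windows.values())
        for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
            if a1 >= b0:
                raise ValueError("region windows must be disjoint and ordered")
        for lo, hi in windows:
            if lo >= hi:
                raise ValueError("region window must have lo < hi")
        self._build_centerline()
        if self.span > self.acquisition_span + 1e-9:
            raise ValueError(
                f"centerline arc length {self.span:.2f} mm exceeds the "
                f"acquisition span {self.acquisition_span} mm"
            )

    # -- centerline ---------------------------------------------------------
    def _build_centerline(self) -> None:
        pts = self.centerline_control_points
        if len(pts) < 4:
            raise ValueError("need at least 4 centerline control points")
        chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        spline = CubicSpline(chord, pts, axis=0)
        u = np.linspace(0.0, chord[-1], 4096)
        dense = spline(u)
        seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        s_dense = np.concatenate([[0.0], np.cumsum(seg)])
        self._span = float(s_dense[-1])
        self._u_of_s = CubicSpline(s_dense, u)
        self._spline = spline

    @property
    def span(self) -> float:
        """Total arc length of the centerline (mm)."""
        return self._span

    def centerline_points(self, s: np.ndarray) -> np.ndarray:
        """Anatomical centerline points at arc lengths ``s`` (mm)."""
        s = np.asarray(s, float)
        return self._spline(self._u_of_s(np.clip(s, 0.0, self.span)))

    # -- cross-section geometry --------------------------------------------
    def area_scale(self, s) -> np.ndarray:
        """State-dependent area scale factor at arc length ``s``.

        Inside a constricted window the factor equals the region's value
        exactly; cosine tapers of width ``taper_mm`` sit *outside* the window
        edges so that window means are not diluted by the transitions.
        """
        s = np.atleast_1d(np.asarray(s, float))
        scale = np.ones_like(s)
        t = self.taper_mm
        for name, fac in self.state_constriction.items():
            if fac == 1.0:
                continue
            lo, hi = self.region_windows[name]
            w = np.zeros_like(s)
            inside = (s >= lo) & (s <= hi)
            w[inside] = 1.0
            ramp_in = (s > lo - t) & (s < lo)
            w[ramp_in] = 0.5 * (1.0 + np.cos(np.pi * (lo - s[ramp_in]) / t))
            ramp_out = (s > hi) & (s < hi + t)
            w[ramp_out] = 0.5 * (1.0 + np.cos(np.pi * (s[ramp_out] - hi) / t))
            scale = scale * (1.0 - (1.0 - fac) * w)
        return scale

    def base_radius(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, float))
        return np.interp(s, self.radius_stations, self.radius_values)

    def radius(self, s) -> np.ndarray:
        """Effective circular radius sqrt(area/pi) at arc length ``s`` (mm)."""
        return self.base_radius(s) * np.sqrt(self.area_scale(s))

    def section_axes(self, s: float) -> tuple[float, float]:
        """Ellipse semi-axes (a, b) of the cross-section at ``s`` (mm)."""
        r = float(np.atleast_1d(self.radius(s))[0])
        e = math.sqrt(self.ellipticity)
        return r * e, r / e

    def catheter_offset(self, s) -> np.ndarray:
        """Catheter eccentricity (ox, oy) in the local section frame (mm)."""
        s = np.atleast_1d(np.asarray(s, float))
        ax, ay = self.offset_amplitude
        ox = ax * np.sin(2.0 * np.pi * 1.5 * s / self.acquisition_span + 0.7)
        oy = ay * np.cos(2.0 * np.pi * 1.1 * s / self.acquisition_span)
        return np.column_stack([ox, oy])

    def true_area(self, s) -> np.ndarray:
        """Analytic cross-sectional area pi*a*b = pi*r^2*scale (mm^2)."""
        return np.pi * self.base_radius(s) ** 2 * self.area_scale(s)

    def wall_distance(self, s: float, theta: np.ndarray) -> np.ndarray:
        """Catheter-to-wall range along each beam direction ``theta`` (mm)."""
        a, b = self.section_axes(s)
        ox, oy = self.catheter_offset(s)[0]
        return ellipse_ray_distance(a, b, ox, oy, theta)


def ellipse_ray_distance(a: float, b: float, ox: float, oy: float, theta) -> np.ndarray:
    """Distance from an interior point (ox, oy) to the ellipse along direction theta.

    The ellipse is ``(x/a)^2 + (y/b)^2 = 1``; for a circle of radius r and a
    point offset by e along +x this reduces to
    ``-e cos(theta) + sqrt(r^2 - e^2 sin^2(theta))``.
    """
    theta = np.asarray(theta, float)
    ux, uy = np.cos(theta), np.sin(theta)
    A = (ux / a) ** 2 + (uy / b) ** 2
    B = 2.0 * (ox * ux / a**2 + oy * uy / b**2)
    Cc = (ox / a) ** 2 + (oy / b) ** 2 - 1.0
    if Cc >= 0:
        raise ValueError("ray origin lies outside the ellipse")
    return (-B + np.sqrt(B * B - 4.0 * A * Cc)) / (2.0 * A)


def make_phantom(state: str, seed: int = 0, **overrides) -> AirwayPhantom:
    """Construct the default phantom in the ``awake`` or ``asleep`` state.

    The asleep phantom is identical to the awake one except that the
    nasopharynx, base-of-tongue, and epiglottic cross-sectional areas are
    scaled by 0.92, 0.44, and 0.68 (radius scaled by the square root).
    """
    labels = ("awake", "asleep")
    if state not in labels:
        raise ValueError(f"unknown state {state!r}; valid states are {labels}")
    constriction = dict(SLEEP_CONSTRICTION) if state == "asleep" else {}
    return AirwayPhantom(state_constriction=constriction, seed=seed, **overrides)


def _station_arcs(phantom: AirwayPhantom, geometry: AcquisitionGeometry) -> np.ndarray:
    spacing = geometry.frame_spacing
    n = int(math.floor(phantom.span / spacing + 1e-9)) + 1
    return np.arange(n) * spacing


def render_bscan(
    phantom: AirwayPhantom,
    geometry: AcquisitionGeometry,
    station_z: float,
    rng: np.random.Generator | None = None,
    params: RenderParams | None = None,
) -> PolarBScan:
    """Render one rotational polar B-scan at arc length ``station_z``.

    Each of the 2000 A-lines carries a specular wall echo at the
    catheter-to-wall range for its beam angle (Gaussian axial PSF), a
    scattering tail decaying into the tissue, multiplicative Rayleigh speckle,
    an additive Gaussian noise floor, and the bright sheath-reflection ring.
    Beams whose wall range exceeds the imaging range record no echo and their
    sector is flagged truth-missing.
    """
    if not (0.0 <= station_z <= phantom.span + 1e-9):
        raise ValueError(
            f"station {station_z} mm outside the phantom span [0, {phantom.span:.2f}] mm"
        )
    params = params or RenderParams()
    frame_index = int(round(station_z / geometry.frame_spacing))
    if rng is None:
        rng = np.random.default_rng([phantom.seed, frame_index])

    theta = 2.0 * np.pi * np.arange(geometry.alines_per_frame) / geometry.alines_per_frame
    d_wall = phantom.wall_distance(station_z, theta)
    valid = d_wall <= geometry.depth_range
    depths = (np.arange(geometry.depth_pixels) + 0.5) * geometry.pixel_pitch

    sigma = geometry.axial_psf_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    dd = depths[None, :] - d_wall[:, None]
    signal = params.echo_amp * np.exp(-0.5 * (dd / sigma) ** 2)
    step = 0.5 * (1.0 + erf(dd / (sigma * math.sqrt(2.0))))
    signal += params.tissue_amp * step * np.exp(-np.maximum(dd, 0.0) / params.atten_mm)
    signal[~valid, :] = 0.0
    if params.sheath:
        ring = params.sheath_amp * np.exp(
            -0.5 * ((depths - params.sheath_radius) / params.sheath_sigma) ** 2
        )
        signal = signal + ring[None, :]
    if params.speckle:
        signal = signal * rng.rayleigh(
            scale=math.sqrt(2.0 / math.pi), size=signal.shape
        )
    floor = rng.normal(params.floor_mean, params.floor_sd, size=signal.shape)
    intensity = np.clip(signal + floor, 0.0, None).astype(np.float32)
    return PolarBScan(intensity, geometry.pixel_pitch, frame_index, station_z, valid)


def iter_pullback(
    phantom: AirwayPhantom,
    geometry: AcquisitionGeometry,
    seed: int = 0,
    params: RenderParams | None = None,
):
    """Yield the pullback's frames in order without holding the stack in memory."""
    rng = np.random.default_rng(seed)
    for s in _station_arcs(phantom, geometry):
        yield render_bscan(phantom, geometry, float(s), rng=rng, params=params)


def catheter_path(phantom: AirwayPhantom, s: np.ndarray) -> np.ndarray:
    """3D catheter positions: centerline plus eccentricity in the local frame."""
    from .reconstruction import rotation_minimizing_frames

    s = np.asarray(s, float)
    pts = phantom.centerline_points(s)
    _, n1, n2 = rotation_minimizing_frames(pts)
    off = phantom.catheter_offset(s)
    return pts + off[:, :1] * n1 + off[:, 1:2] * n2


def tracker_samples(
    phantom: AirwayPhantom,
    geometry: AcquisitionGeometry,
    tracker_noise_sd: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Electromagnetic-tracker pass: noisy catheter positions per frame station."""
    if tracker_noise_sd < 0:
        raise ValueError("tracker_noise_sd must be >= 0")
    s = _station_arcs(phantom, geometry)
    tracker = catheter_path(phantom, s)
    if tracker_noise_sd > 0:
        rng = np.random.default_rng([seed, 1])
        tracker = tracker + rng.normal(0.0, tracker_noise_sd, size=tracker.shape)
    return tracker


def simulate_pullback(
    phantom: AirwayPhantom,
    geometry: AcquisitionGeometry,
    tracker_noise_sd: float = 0.1,
    seed: int = 0,
    params: RenderParams | None = None,
) -> tuple[list[PolarBScan], np.ndarray]:
    """Render the full pullback stack and the noisy tracker samples.

    Frames are spaced exactly ``pullback_speed / frames_per_s`` apart
    (0.5 mm by default); the tracker pass samples the catheter path at every
    frame station with isotropic Gaussian noise of sd ``tracker_noise_sd``.
    """
    stack = list(iter_pullback(phantom, geometry, seed=seed, params=params))
    tracker = tracker_samples(phantom, geometry, tracker_noise_sd, seed)
    return stack, tracker


def ground_truth(
    phantom: AirwayPhantom,
    geometry: AcquisitionGeometry,
    n_vertices: int = 256,
):
    """Analytic per-station areas and a watertight truth mesh.

    Returns ``(surface, stations_mm, areas_mm2)`` where areas are the exact
    ellipse areas pi*a*b at each frame station and the surface is a loft of
    the analytic contours on the anatomical centerline.
    """
    from .reconstruction import Centerline, loft_rings, rotation_minimizing_frames

    s = _station_arcs(phantom, geometry)
    areas = phantom.true_area(s)
    pts = phantom.centerline_points(s)
    t, n1, n2 = rotation_minimizing_frames(pts)
    cl = Centerline(points=pts, arc_length=s, tangent=t, normal1=n1, normal2=n2)
    theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    rings = []
    for si in s:
        a, b = phantom.section_axes(float(si))
        rings.append(np.column_stack([a * np.cos(theta), b * np.sin(theta)]))
    surface = loft_rings(rings, cl)
    return surface, s, areas
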