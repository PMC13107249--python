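"""Curved 3D lumen reconstruction from contours and tracker coordinates.

The catheter records planar contours; the electromagnetic tracker records the
3D path the catheter followed.  Reconstruction smooths the tracker samples
into an arc-length-parameterized centerline, transports a twist-free
(rotation-minimizing) orthonormal frame along it, rigidly places each contour
in its station's normal plane, and stitches the stack into a watertight
triangulated surface.  It also provides per-station cross-sectional areas and
the awake-vs-asleep regional comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.interpolate import CubicSpline, UnivariateSpline
from shapely.geometry import LinearRing

from .segmentation import LumenContour

__all__ = [
    "Centerline",
    "AirwaySurface",
    "smooth_centerline",
    "rotation_minimizing_frames",
    "frames_along_centerline",
    "loft_rings",
    "loft_surface",
    "cross_sectional_area",
    "compare_states",
]


@dataclass
class Centerline:
    """Smoothed catheter path resampled at uniform arc-length stations."""

    points: np.ndarray                       # (n, 3) mm
    arc_length: np.ndarray                   # (n,) cumulative mm
    tangent: np.ndarray | None = None        # (n, 3)
    normal1: np.ndarray | None = None
    normal2: np.ndarray | None = None
    residual_rms: float = 0.0                # spline fit residual vs raw samples

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        self.arc_length = np.asarray(self.arc_length, float)
        if self.points.shape != (len(self.arc_length), 3):
            raise ValueError("points must be (n, 3) with one arc length per point")

    @property
    def n_stations(self) -> int:
        return len(self.points)

    @property
    def spacing(self) -> float:
        return float(np.diff(self.arc_length).mean()) if self.n_stations > 1 else 0.0

    @property
    def has_frames(self) -> bool:
        return self.tangent is not None


@dataclass
class AirwaySurface:
    """Watertight triangulated lumen wall in anatomical coordinates."""

    mesh: trimesh.Trimesh
    station_of_vertex: np.ndarray            # ring index per vertex (-1 for cap apexes)
    stations: np.ndarray = field(default_factory=lambda: np.empty(0))  # arc length per ring

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices

    @property
    def triangles(self) -> np.ndarray:
        return self.mesh.faces

    @property
    def is_watertight(self) -> bool:
        return bool(self.mesh.is_watertight)

    @property
    def volume(self) -> float:
        return float(abs(self.mesh.volume))


def smooth_centerline(
    samples: np.ndarray,
    spacing: float = 0.5,
    smooth_mm: float | None = None,
) -> Centerline:
    """Fit a smoothing spline to tracker samples; resample at uniform arc length.

    ``smooth_mm`` is the expected per-sample positional noise (mm); the spline
    smoothing factor is ``n * smooth_mm**2`` per coordinate.  ``None`` lets
    the fit pass close to the samples (interpolating for noiseless input).
    """
    samples = np.asarray(samples, float)
    if samples.ndim != 2 or samples.shape[1] != 3 or len(samples) < 4:
        raise ValueError("need at least 4 tracker samples of shape (n, 3)")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(samples, axis=0), axis=1))]
    )
    if np.any(np.diff(chord) <= 0):
        keep = np.concatenate([[True], np.diff(chord) > 0])
        samples, chord = samples[keep], chord[keep]
    s_factor = 0.0 if smooth_mm is None else len(samples) * smooth_mm**2
    splines = [
        UnivariateSpline(chord, samples[:, k], k=3, s=s_factor) for k in range(3)
    ]
    # reparameterize by arc length of the smoothed curve
    u = np.linspace(chord[0], chord[-1], max(4096, 8 * len(samples)))
    dense = np.column_stack([sp(u) for sp in splines])
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s_dense = np.concatenate([[0.0], np.cumsum(seg)])
    total = s_dense[-1]
    n = int(np.floor(total / spacing + 1e-9)) + 1
    s_out = np.arange(n) * spacing
    u_of_s = CubicSpline(s_dense, u)
    points = np.column_stack([sp(u_of_s(s_out)) for sp in splines])
    fitted = np.column_stack([sp(chord) for sp in splines])
    rms = float(np.sqrt(np.mean(np.sum((fitted - samples) ** 2, axis=1))))
    return Centerline(points=points, arc_length=s_out, residual_rms=rms)


def rotation_minimizing_frames(
    points: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Twist-free orthonormal frames along a polyline (double-reflection method).

    Returns (tangent, normal1, normal2) arrays of shape (n, 3).  The first
    normal is the projection of the world x-axis onto the first normal plane
    (falling back to the y-axis near degeneracy), and subsequent normals are
    transported without spurious rotation about the tangent.
    """
    points = np.asarray(points, float)
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    tangent = np.gradient(points, axis=0)
    norms = np.linalg.norm(tangent, axis=1)
    if np.any(norms < 1e-14):
        raise ValueError("zero-length tangent encountered")
    tangent = tangent / norms[:, None]

    ref = np.array([1.0, 0.0, 0.0])
    r0 = ref - np.dot(ref, tangent[0]) * tangent[0]
    if np.linalg.norm(r0) < 1e-8:
        ref = np.array([0.0, 1.0, 0.0])
        r0 = ref - np.dot(ref, tangent[0]) * tangent[0]
    r0 /= np.linalg.norm(r0)

    normal1 = np.empty_like(points)
    normal1[0] = r0
    for i in range(n - 1):
        # double reflection (Wang et al. 2008): reflect across the chord
        # bisector plane, then across the next tangent's bisector plane
        v1 = points[i + 1] - points[i]
        c1 = np.dot(v1, v1)
        if c1 < 1e-20:
            normal1[i + 1] = normal1[i]
            continue
        rl = normal1[i] - (2.0 / c1) * np.dot(v1, normal1[i]) * v1
        tl = tangent[i] - (2.0 / c1) * np.dot(v1, tangent[i]) * v1
        v2 = tangent[i + 1] - tl
        c2 = np.dot(v2, v2)
        if c2 < 1e-20:
            normal1[i + 1] = rl
        else:
            normal1[i + 1] = rl - (2.0 / c2) * np.dot(v2, rl) * v2
        # re-orthonormalize against accumulated drift
        normal1[i + 1] -= np.dot(normal1[i + 1], tangent[i + 1]) * tangent[i + 1]
        normal1[i + 1] /= np.linalg.norm(normal1[i + 1])
    normal2 = np.cross(tangent, normal1)
    return tangent, normal1, normal2


def frames_along_centerline(centerline: Centerline) -> Centerline:
    """Attach rotation-minimizing frames to a smoothed centerline."""
    t, n1, n2 = rotation_minimizing_frames(centerline.points)
    return Centerline(
        points=centerline.points,
        arc_length=centerline.arc_length,
        tangent=t,
        normal1=n1,
        normal2=n2,
        residual_rms=centerline.residual_rms,
    )


def _resample_ring(vertices: np.ndarray, n_out: int) -> np.ndarray:
    """Angularly resample a star-shaped (catheter-centered) ring to n_out vertices."""
    n_in = len(vertices)
    if n_in == n_out:
        return vertices
    theta_in = np.arctan2(vertices[:, 1], vertices[:, 0]) % (2 * np.pi)
    order = np.argsort(theta_in)
    th = theta_in[order]
    r = np.hypot(vertices[order, 0], vertices[order, 1])
    th_ext = np.concatenate([th, th[:1] + 2 * np.pi])
    r_ext = np.concatenate([r, r[:1]])
    theta_out = 2.0 * np.pi * np.arange(n_out) / n_out
    th_q = np.where(theta_out < th[0], theta_out + 2 * np.pi, theta_out)
    r_out = np.interp(th_q, th_ext, r_ext)
    return np.column_stack([r_out * np.cos(theta_out), r_out * np.sin(theta_out)])


def _best_roll(prev_world: np.ndarray, cur_world: np.ndarray) -> int:
    """Cyclic vertex shift minimizing summed squared distance between rings."""
    n = len(prev_world)
    corr = np.zeros(n)
    for k in range(3):
        fa = np.fft.rfft(cur_world[:, k])
        fb = np.fft.rfft(prev_world[:, k])
        corr += np.fft.irfft(fb * np.conj(fa), n=n)
    shift = int(np.argmax(corr))
    return shift


def loft_rings(
    rings: list[np.ndarray],
    centerline: Centerline,
    roll_register: bool = True,
) -> AirwaySurface:
    """Stitch planar rings placed on the centerline's frames into a closed mesh.

    Each ring is a (n, 2) vertex array in its station's (normal1, normal2)
    plane with the catheter center at the centerline point.  Consecutive rings
    are roll-registered by the cyclic shift minimizing summed vertex distance,
    stitched with triangle strips, and the ends are capped with vertex fans.
    """
    if not centerline.has_frames:
        centerline = frames_along_centerline(centerline)
    if len(rings) != centerline.n_stations:
        raise ValueError(
            f"{len(rings)} rings but {centerline.n_stations} centerline stations"
        )
    n = len(rings[0])
    if any(len(r) != n for r in rings):
        raise ValueError("all rings must share the same vertex count")

    placed = []
    roll_offsets = np.zeros(len(rings), dtype=int)
    for i, ring in enumerate(rings):
        p = centerline.points[i]
        world = (
            p[None, :]
            + ring[:, :1] * centerline.normal1[i][None, :]
            + ring[:, 1:2] * centerline.normal2[i][None, :]
        )
        if roll_register and i > 0:
            shift = _best_roll(placed[-1], world)
            if shift:
                world = np.roll(world, shift, axis=0)
            roll_offsets[i] = shift
        placed.append(world)

    vertices = np.vstack(placed)
    station_of_vertex = np.repeat(np.arange(len(rings)), n)
    faces = []
    for i in range(len(rings) - 1):
        a = i * n + np.arange(n)
        b = (i + 1) * n + np.arange(n)
        an, bn = np.roll(a, -1), np.roll(b, -1)
        faces.append(np.column_stack([a, b, an]))
        faces.append(np.column_stack([an, b, bn]))
    faces = np.vstack(faces)

    # end caps: fan to the ring centroid
    c0 = placed[0].mean(axis=0)
    c1 = placed[-1].mean(axis=0)
    i0, i1 = len(vertices), len(vertices) + 1
    vertices = np.vstack([vertices, c0[None, :], c1[None, :]])
    station_of_vertex = np.concatenate([station_of_vertex, [-1, -1]])
    a = np.arange(n)
    cap0 = np.column_stack([np.full(n, i0), np.roll(a, -1), a])
    last = (len(rings) - 1) * n + np.arange(n)
    cap1 = np.column_stack([np.full(n, i1), last, np.roll(last, -1)])
    faces = np.vstack([faces, cap0, cap1])

    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    surface = AirwaySurface(
        mesh=mesh, station_of_vertex=station_of_vertex, stations=centerline.arc_length
    )
    surface.roll_offsets = roll_offsets
    return surface


def loft_surface(
    contours: list[LumenContour],
    centerline: Centerline,
    trim: tuple[float, float] = (5.0, 5.0),
    vertices_per_station: int | None = 256,
    extension_mm: float = 0.0,
) -> AirwaySurface:
    """Place contours on the centerline, trim the ends, and loft a closed mesh.

    ``trim`` removes the stated arc length from the proximal and distal ends
    before lofting (the raw pullback overshoots the anatomy of interest).
    Contours are matched to centerline stations by order; rings are optionally
    resampled to ``vertices_per_station`` vertices for a lighter mesh.
    ``extension_mm`` appends straight constant-section flow extensions along
    the end tangents (standard CFD practice: keeps inlet/outlet boundary
    adjustment layers outside the anatomical span).
    """
    if len(contours) != centerline.n_stations:
        raise ValueError(
            f"{len(contours)} contours but {centerline.n_stations} stations"
        )
    n0 = contours[0].n_vertices
    if any(c.n_vertices != n0 for c in contours):
        raise ValueError("contour vertex counts differ")
    lo = trim[0]
    hi = centerline.arc_length[-1] - trim[1]
    keep = (centerline.arc_length >= lo - 1e-9) & (centerline.arc_length <= hi + 1e-9)
    if keep.sum() < 2:
        raise ValueError("trim leaves fewer than 2 stations")
    cl = Centerline(
        points=centerline.points[keep],
        arc_length=centerline.arc_length[keep],
        residual_rms=centerline.residual_rms,
    )
    cl = frames_along_centerline(cl)
    kept = [c for c, k in zip(contours, keep) if k]
    if any(np.isnan(c.vertices).any() for c in kept):
        raise ValueError("contours contain unfilled (NaN) vertices; fill first")
    n_out = vertices_per_station or n0
    rings = [_resample_ring(c.vertices, n_out) for c in kept]
    if extension_mm > 0:
        spacing = float(np.diff(cl.arc_length).mean())
        k = max(int(round(extension_mm / spacing)), 1)
        t0 = cl.points[1] - cl.points[0]
        t0 /= np.linalg.norm(t0)
        t1 = cl.points[-1] - cl.points[-2]
        t1 /= np.linalg.norm(t1)
        pre = [cl.points[0] - (k - i) * spacing * t0 for i in range(k)]
        post = [cl.points[-1] + (i + 1) * spacing * t1 for i in range(k)]
        pts = np.vstack([pre, cl.points, post])
        arcs = np.concatenate(
            [
                cl.arc_length[0] - spacing * np.arange(k, 0, -1),
                cl.arc_length,
                cl.arc_length[-1] + spacing * np.arange(1, k + 1),
            ]
        )
        cl = frames_along_centerline(Centerline(points=pts, arc_length=arcs))
        rings = [rings[0]] * k + rings + [rings[-1]] * k
    surface = loft_rings(rings, cl)
    _warn_tight_bends(cl, rings)
    return surface


def _warn_tight_bends(cl: Centerline, rings: list[np.ndarray]) -> None:
    """Warn where adjacent section planes intersect inside the lumen."""
    if cl.n_stations < 2:
        return
    max_r = np.array([np.hypot(r[:, 0], r[:, 1]).max() for r in rings])
    dt = np.linalg.norm(np.diff(cl.tangent, axis=0), axis=1)
    ds = np.diff(cl.arc_length)
    # curvature ~ |dT|/ds; planes cross inside the lumen when 1/kappa < r_max
    kappa = dt / np.maximum(ds, 1e-12)
    bad = np.where(kappa * np.maximum(max_r[:-1], max_r[1:]) > 1.0)[0]
    if len(bad):
        warnings.warn(
            f"section planes may self-intersect at stations {bad.tolist()}",
            RuntimeWarning,
            stacklevel=3,
        )


def cross_sectional_area(contour: LumenContour | np.ndarray) -> float:
    """Shoelace area (mm^2) of a closed simple polygon.

    Accepts a :class:`LumenContour` or a raw (n, 2) vertex array; raises for
    self-intersecting polygons.  The absolute value is returned so vertex
    orientation does not matter.
    """
    verts = contour.vertices if isinstance(contour, LumenContour) else np.asarray(contour, float)
    if len(verts) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    if np.isnan(verts).any():
        raise ValueError("polygon contains NaN vertices")
    if not LinearRing(verts).is_simple:
        raise ValueError("polygon is self-intersecting")
    x, y = verts[:, 0], verts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) / 2.0)


def area_profile(contours: list[LumenContour]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-station (z, area, extrapolated fraction) for a contour stack."""
    z = np.array([c.z_mm for c in contours])
    areas = np.array([cross_sectional_area(c) for c in contours])
    frac = np.array([c.extrapolated_fraction for c in contours])
    return z, areas, frac


def compare_states(
    z_awake: np.ndarray,
    areas_awake: np.ndarray,
    z_asleep: np.ndarray,
    areas_asleep: np.ndarray,
    region_windows: dict[str, tuple[float, float]],
) -> dict[str, float]:
    """Per-region percent reduction in mean cross-sectional area awake -> asleep.

    Both profiles are resampled onto the awake arc-length grid; for each
    region window the reduction is ``100 * (1 - mean_asleep / mean_awake)``
    over stations inside the window.  Negative values (expansion) are allowed.
    """
    z_awake = np.asarray(z_awake, float)
    areas_awake = np.asarray(areas_awake, float)
    asleep_on_awake = np.interp(z_awake, np.asarray(z_asleep, float), np.asarray(areas_asleep, float))
    out: dict[str, float] = {}
    for name, (lo, hi) in region_windows.items():
        sel = (z_awake >= lo) & (z_awake <= hi)
        if not sel.any():
            raise ValueError(f"region window {name!r} [{lo}, {hi}] contains no stations")
        mw = areas_awake[sel].mean()
        ma = asleep_on_awake[sel].mean()
        out[name] = float(100.0 * (1.0 - ma / mw))
    return out
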