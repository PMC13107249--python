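"""End-to-end pipeline: phantom pair -> imaging -> segmentation ->
reconstruction -> state comparison -> airflow -> obstruction localization.

One :class:`PipelineConfig` (YAML-serializable, single global seed) drives
every stage; :func:`run_pipeline` streams the pullback frame by frame so the
full-resolution stacks never need to sit in memory, and writes every artifact
plus the resolved config next to the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as afio
from .flow_lbm import SimConfig, run_simulation, voxelize
from .imaging import mask_sheath_artifact, wall_signature, _circular_shift_estimate
from .obstruction import default_stations, localize
from .phantom import (
    AcquisitionGeometry,
    iter_pullback,
    make_phantom,
    tracker_samples,
)
from .reconstruction import (
    Centerline,
    area_profile,
    compare_states,
    frames_along_centerline,
    loft_surface,
    smooth_centerline,
)
from .segmentation import LumenContour, SegmentationParams, contour_from_frame, fill_missing_sectors

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("airwayflow")


@dataclass
class PipelineConfig:
    """Resolved settings for one reproducible pipeline run."""

    seed: int = 0
    tracker_noise_sd: float = 0.1
    mask_band: tuple[float, float] = (0.7, 1.1)
    align: bool = True
    use_truth_contours: bool = False
    trim: tuple[float, float] = (5.0, 5.0)
    smooth_mm: float = 0.1
    vertices_per_station: int = 256
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    run_flow: bool = False
    flow_states: tuple[str, ...] = ("asleep",)
    flow_dx_mm: float = 0.75
    flow_extension_mm: float = 20.0
    inflow_lpm: float = 9.45
    re_target: float = 100.0
    collision: str = "mrt"
    flow_mode: str = "steady"
    flow_max_steps: int = 60000
    flow_conv_tol: float = 1e-6
    n_stations: int = 7

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mask_band"] = list(self.mask_band)
        d["trim"] = list(self.trim)
        d["flow_states"] = list(self.flow_states)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        seg = d.pop("segmentation", None)
        cfg = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if seg is not None:
            cfg.segmentation = SegmentationParams(**seg)
        cfg.mask_band = tuple(cfg.mask_band)
        cfg.trim = tuple(cfg.trim)
        cfg.flow_states = tuple(cfg.flow_states)
        return cfg


def _anatomical_stations(
    region_windows: dict[str, tuple[float, float]], lo: float, hi: float
) -> np.ndarray:
    """Anatomical-landmark stations: one per region center plus the trimmed ends.

    Mirrors clinical practice (points of interest at named pharyngeal levels)
    rather than equal spacing: a station at each region center guarantees the
    three-point curvature stencil brackets any one region's constriction.
    """
    centers = [0.5 * (a + b) for a, b in region_windows.values() if lo < 0.5 * (a + b) < hi]
    return np.array(sorted({lo, hi, *centers}))


def _truth_contours(phantom, geometry) -> list[LumenContour]:
    """Analytic catheter-centered contours, bypassing rendering/segmentation."""
    spacing = geometry.frame_spacing
    n = int(np.floor(phantom.span / spacing + 1e-9)) + 1
    theta = 2.0 * np.pi * np.arange(geometry.alines_per_frame) / geometry.alines_per_frame
    out = []
    for i in range(n):
        s = i * spacing
        d = phantom.wall_distance(s, theta)
        verts = np.column_stack([d * np.cos(theta), d * np.sin(theta)])
        out.append(
            LumenContour(
                frame_index=i,
                z_mm=s,
                vertices=verts,
                valid=d <= geometry.depth_range,
            )
        )
    return out


def _segment_state(phantom, geometry, config: PipelineConfig) -> list[LumenContour]:
    """Stream the pullback: render, mask, (align), segment each frame."""
    if config.use_truth_contours:
        return _truth_contours(phantom, geometry)
    contours = []
    prev_sig = None
    cum = 0
    for frame in iter_pullback(phantom, geometry, seed=config.seed):
        frame = mask_sheath_artifact(frame, config.mask_band)
        if config.align:
            sig = wall_signature(frame, config.segmentation.exclusion_mm)
            if prev_sig is not None:
                cum += _circular_shift_estimate(prev_sig, np.roll(sig, cum))
                if cum:
                    frame = dataclasses.replace(
                        frame,
                        intensity=np.roll(frame.intensity, cum, axis=0),
                        sector_valid=np.roll(frame.sector_valid, cum),
                    )
            prev_sig = np.roll(sig, cum)
        contours.append(contour_from_frame(frame, config.segmentation))
    return contours


def _reconstruct_state(phantom, geometry, contours, config: PipelineConfig):
    tracker = tracker_samples(
        phantom, geometry, tracker_noise_sd=config.tracker_noise_sd, seed=config.seed
    )
    cl = smooth_centerline(tracker, spacing=geometry.frame_spacing, smooth_mm=config.smooth_mm)
    n = min(len(contours), cl.n_stations)
    cl = Centerline(points=cl.points[:n], arc_length=cl.arc_length[:n], residual_rms=cl.residual_rms)
    cl = frames_along_centerline(cl)
    contours = contours[:n]
    z, areas, frac = area_profile(contours)
    return tracker, cl, contours, (z, areas, frac)


def run_pipeline(config: PipelineConfig, out_dir=None, geometry: AcquisitionGeometry | None = None) -> dict:
    """Execute the full awake/asleep pipeline and return the report dict.

    Stages: phantom pair -> streamed preprocessing and segmentation ->
    sector filling -> centerline smoothing -> per-station areas ->
    regional awake/asleep comparison -> (optional) lofted-mesh LBM airflow
    and pressure-derivative obstruction localization.
    """
    geometry = geometry or AcquisitionGeometry()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {"seed": config.seed, "stages": {}}
    timings: dict = {}
    states = {}
    for state in ("awake", "asleep"):
        t0 = time.time()
        phantom = make_phantom(state, config.seed)
        contours = _segment_state(phantom, geometry, config)
        contours = fill_missing_sectors(contours)
        tracker, cl, contours, (z, areas, frac) = _reconstruct_state(
            phantom, geometry, contours, config
        )
        states[state] = {
            "phantom": phantom,
            "contours": contours,
            "centerline": cl,
            "tracker": tracker,
            "z": z,
            "areas": areas,
            "frac": frac,
        }
        report["stages"][f"segment_{state}"] = {
            "n_frames": len(contours),
            "mean_extrapolated_fraction": float(np.mean(frac)),
        }
        timings[f"segment_{state}_s"] = round(time.time() - t0, 2)
        log.info("segmented %s: %d frames in %.1fs", state, len(contours), time.time() - t0)
        if out is not None:
            afio.write_contours_json(out / f"contours_{state}.json", contours)
            afio.write_areas_csv(out / f"areas_{state}.csv", z, areas, frac)
            afio.write_tracker_csv(out / f"tracker_{state}.csv", tracker)
            afio.write_centerline_csv(out / f"centerline_{state}.csv", cl)

    windows = states["awake"]["phantom"].region_windows
    reductions = compare_states(
        states["awake"]["z"],
        states["awake"]["areas"],
        states["asleep"]["z"],
        states["asleep"]["areas"],
        windows,
    )
    report["region_reductions_pct"] = {k: round(v, 3) for k, v in reductions.items()}

    if config.run_flow:
        for state in config.flow_states:
            t0 = time.time()
            st = states[state]
            surface = loft_surface(
                st["contours"],
                st["centerline"],
                trim=config.trim,
                vertices_per_station=config.vertices_per_station,
                extension_mm=config.flow_extension_mm,
            )
            lattice = voxelize(surface, config.flow_dx_mm)
            sim = SimConfig(
                re_target=config.re_target,
                collision=config.collision,
                max_steps=config.flow_max_steps,
                conv_tol=config.flow_conv_tol,
            )
            fld = run_simulation(lattice, config.inflow_lpm, mode=config.flow_mode, config=sim)
            lo, hi = config.trim[0], st["centerline"].arc_length[-1] - config.trim[1]
            stations = _anatomical_stations(st["phantom"].region_windows, lo, hi)
            if len(stations) != config.n_stations:
                stations = default_stations(lo, hi, config.n_stations)
            profile = localize(
                fld,
                st["centerline"],
                stations_mm=stations,
                areas=(st["z"], st["areas"]),
            )
            umag = np.sqrt(np.nansum(fld.velocity_ms() ** 2, axis=0))
            timings[f"flow_{state}_s"] = round(time.time() - t0, 2)
            report["stages"][f"flow_{state}"] = {
                "reynolds": round(fld.meta["reynolds"], 2),
                "tau": round(fld.meta["tau"], 5),
                "steps": fld.meta["steps_total"],
                "converged": fld.meta.get("converged"),
                "peak_velocity_m_s": round(float(np.nanmax(umag)), 5),
                "mean_inlet_velocity_m_s": round(fld.meta["u_inlet_phys_m_s"], 5),
            }
            report[f"obstruction_{state}"] = {
                "dominant_site": profile.dominant_site,
                "dominant_z_mm": float(
                    profile.stations_mm[profile.labels.index(profile.dominant_site)]
                ),
                "ranking": profile.ranking,
                "no_focal_obstruction": profile.no_focal_obstruction,
                "table": profile.to_frame().round(6).to_dict(orient="list"),
            }
            if out is not None:
                afio.write_mesh_stl(out / f"airway_{state}.stl", surface)
                afio.write_mesh_vtk(out / f"airway_{state}.vtk", surface)
                afio.write_flowfield_npz(out / f"flow_{state}.npz", fld)
                afio.write_flowfield_vtk(out / f"flow_{state}.vtk", fld)
                profile.to_frame().to_csv(out / f"obstruction_{state}.csv", index=False)

    if out is not None:
        afio.write_yaml(out / "config_resolved.yaml", config.to_dict())
        # the report holds numeric results only and is byte-reproducible for a
        # given config + seed; wall-clock timings go in a sidecar
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
        (out / "timings.json").write_text(json.dumps(timings, sort_keys=True, indent=1))
    return report
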