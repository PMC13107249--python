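"""Readers and writers for every pipeline artifact.

Formats: B-scan stacks as a compressed numpy archive (lossless round trip)
with an optional 16-bit multi-page TIFF export for viewing; contours as JSON
or flat CSV; centerlines, tracker samples, and area profiles as CSV; meshes
as binary STL and legacy-ASCII VTK PolyData; flow fields as legacy-ASCII VTK
structured points plus a numpy archive; configs as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh
import yaml

from .flow_lbm import FlowField, VoxelLattice
from .imaging import PolarBScan
from .reconstruction import AirwaySurface, Centerline
from .segmentation import LumenContour

__all__ = [
    "write_stack",
    "read_stack",
    "write_stack_tiff",
    "write_contours_json",
    "read_contours_json",
    "write_contours_csv",
    "write_centerline_csv",
    "read_centerline_csv",
    "write_tracker_csv",
    "read_tracker_csv",
    "write_areas_csv",
    "read_areas_csv",
    "write_mesh_stl",
    "read_mesh_stl",
    "write_mesh_vtk",
    "write_flowfield_vtk",
    "write_flowfield_npz",
    "read_flowfield_npz",
    "write_yaml",
    "read_yaml",
]


# -- B-scan stacks ----------------------------------------------------------

def write_stack(path, stack: list[PolarBScan]) -> None:
    """Lossless stack archive: intensities, validity flags, and calibration."""
    np.savez_compressed(
        path,
        intensity=np.stack([f.intensity for f in stack]),
        sector_valid=np.stack([f.sector_valid for f in stack]),
        pixel_pitch=np.array([stack[0].pixel_pitch]),
        frame_index=np.array([f.frame_index for f in stack]),
        z_nominal=np.array([f.z_nominal for f in stack]),
    )


def read_stack(path) -> list[PolarBScan]:
    with np.load(path) as d:
        pitch = float(d["pixel_pitch"][0])
        return [
            PolarBScan(
                d["intensity"][i],
                pitch,
                int(d["frame_index"][i]),
                float(d["z_nominal"][i]),
                d["sector_valid"][i],
            )
            for i in range(len(d["frame_index"]))
        ]


def write_stack_tiff(path, stack: list[PolarBScan]) -> None:
    """16-bit multi-page TIFF export (viewing only; globally rescaled)."""
    data = np.stack([f.intensity for f in stack])
    peak = float(data.max()) or 1.0
    scaled = np.clip(data / peak * 65535.0, 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        scaled,
        metadata={
            "pixel_pitch_mm": stack[0].pixel_pitch,
            "intensity_scale": peak / 65535.0,
        },
    )


# -- contours ---------------------------------------------------------------

def write_contours_json(path, contours: list[LumenContour]) -> None:
    payload = [
        {
            "frame_index": c.frame_index,
            "z_mm": c.z_mm,
            "vertices": c.vertices.tolist(),
            "valid": c.valid.astype(int).tolist(),
            "usable": bool(c.usable),
        }
        for c in contours
    ]
    Path(path).write_text(json.dumps(payload))


def read_contours_json(path) -> list[LumenContour]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed contour JSON {path}: {e}") from e
    out = []
    for i, rec in enumerate(payload):
        for key in ("frame_index", "z_mm", "vertices", "valid"):
            if key not in rec:
                raise ValueError(f"contour record {i} in {path} missing field {key!r}")
        out.append(
            LumenContour(
                frame_index=int(rec["frame_index"]),
                z_mm=float(rec["z_mm"]),
                vertices=np.asarray(rec["vertices"], float),
                valid=np.asarray(rec["valid"], bool),
                usable=bool(rec.get("usable", True)),
            )
        )
    return out


def write_contours_csv(path, contours: list[LumenContour]) -> None:
    rows = []
    for c in contours:
        for j, (x, y) in enumerate(c.vertices):
            rows.append((c.frame_index, c.z_mm, j, x, y, int(c.valid[j])))
    pd.DataFrame(
        rows, columns=["frame_index", "z_mm", "vertex", "x_mm", "y_mm", "valid"]
    ).to_csv(path, index=False)


# -- centerline / tracker / areas ------------------------------------------

def write_centerline_csv(path, cl: Centerline) -> None:
    pd.DataFrame(
        {
            "s_mm": cl.arc_length,
            "x_mm": cl.points[:, 0],
            "y_mm": cl.points[:, 1],
            "z_mm": cl.points[:, 2],
        }
    ).to_csv(path, index=False)


def read_centerline_csv(path) -> Centerline:
    df = pd.read_csv(path)
    for col in ("s_mm", "x_mm", "y_mm", "z_mm"):
        if col not in df:
            raise ValueError(f"centerline CSV {path} missing column {col!r}")
    return Centerline(
        points=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        arc_length=df["s_mm"].to_numpy(),
    )


def write_tracker_csv(path, tracker: np.ndarray) -> None:
    pd.DataFrame(
        {
            "frame_index": np.arange(len(tracker)),
            "x_mm": tracker[:, 0],
            "y_mm": tracker[:, 1],
            "z_mm": tracker[:, 2],
        }
    ).to_csv(path, index=False)


def read_tracker_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x_mm", "y_mm", "z_mm"]].to_numpy()


def write_areas_csv(path, z_mm, area_mm2, pct_extrapolated=None) -> None:
    pct = np.zeros(len(z_mm)) if pct_extrapolated is None else np.asarray(pct_extrapolated)
    pd.DataFrame(
        {"station_z_mm": z_mm, "area_mm2": area_mm2, "pct_extrapolated": 100.0 * pct}
    ).to_csv(path, index=False)


def read_areas_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["station_z_mm"].to_numpy(), df["area_mm2"].to_numpy()


# -- meshes -----------------------------------------------------------------

def write_mesh_stl(path, surface: AirwaySurface | trimesh.Trimesh) -> None:
    mesh = surface.mesh if isinstance(surface, AirwaySurface) else surface
    mesh.export(path, file_type="stl")


def read_mesh_stl(path) -> trimesh.Trimesh:
    mesh = trimesh.load(path, file_type="stl", process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a single triangle mesh")
    return mesh


def write_mesh_vtk(path, surface: AirwaySurface | trimesh.Trimesh) -> None:
    """Legacy-ASCII VTK PolyData (readable by ParaView and friends)."""
    mesh = surface.mesh if isinstance(surface, AirwaySurface) else surface
    v, f = mesh.vertices, mesh.faces
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nairwayflow surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} float\n")
        np.savetxt(fh, v, fmt="%.6f")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        np.savetxt(fh, np.column_stack([np.full(len(f), 3), f]), fmt="%d")


# -- flow fields ------------------------------------------------------------

def write_flowfield_vtk(path, field: FlowField) -> None:
    """Legacy-ASCII VTK structured points with occupancy, pressure, velocity."""
    lat = field.lattice
    nx, ny, nz = lat.occupancy.shape
    p = field.pressure_pa()
    u = field.velocity_ms()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nairwayflow flow field\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        o = lat.origin + 0.5 * lat.dx
        fh.write(f"ORIGIN {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}\n")
        fh.write(f"SPACING {lat.dx:.6f} {lat.dx:.6f} {lat.dx:.6f}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write("SCALARS occupancy int 1\nLOOKUP_TABLE default\n")
        lat.occupancy.transpose(2, 1, 0).ravel().tofile(fh, sep="\n", format="%d")
        fh.write("\nSCALARS pressure_pa float 1\nLOOKUP_TABLE default\n")
        np.nan_to_num(p).transpose(2, 1, 0).ravel().tofile(fh, sep="\n", format="%.6e")
        fh.write("\nVECTORS velocity_m_s float\n")
        vec = np.nan_to_num(u).transpose(0, 3, 2, 1).reshape(3, -1).T
        np.savetxt(fh, vec, fmt="%.6e")


def write_flowfield_npz(path, field: FlowField) -> None:
    np.savez_compressed(
        path,
        occupancy=field.lattice.occupancy,
        origin=field.lattice.origin,
        dx_mm=np.array([field.dx_mm]),
        dt_s=np.array([field.dt_s]),
        rho0=np.array([field.rho0]),
        rho=field.rho,
        u=field.u,
        meta=np.array([json.dumps(field.meta, default=_json_default)]),
    )


def read_flowfield_npz(path) -> FlowField:
    with np.load(path, allow_pickle=False) as d:
        lat = VoxelLattice(d["occupancy"], float(d["dx_mm"][0]), d["origin"])
        return FlowField(
            lattice=lat,
            rho=d["rho"],
            u=d["u"],
            dx_mm=float(d["dx_mm"][0]),
            dt_s=float(d["dt_s"][0]),
            rho0=float(d["rho0"][0]),
            meta=json.loads(str(d["meta"][0])),
        )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# -- config -----------------------------------------------------------------

def write_yaml(path, payload: dict) -> None:
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_yaml(path) -> dict:
    try:
        out = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise ValueError(f"malformed YAML {path}: {e}") from e
    if not isinstance(out, dict):
        raise ValueError(f"YAML {path} must contain a mapping at top level")
    return out
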