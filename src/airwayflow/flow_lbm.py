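"""D3Q19 lattice-Boltzmann airflow solver with SRT and MRT collisions.

The reconstructed lumen is voxelized onto a uniform grid and air flow is
simulated with the lattice-Boltzmann method: D3Q19 velocity set, BGK
(single-relaxation-time) or d'Humieres multi-relaxation-time collision,
halfway bounce-back no-slip walls, a velocity (plug) inlet and a
fixed-density outlet imposed by non-equilibrium extrapolation.  Runs are
performed at desk-scale Reynolds numbers (viscosity inflated, geometry
preserved) with the physical-unit bookkeeping — dx, dt, tau, Re — recorded
alongside every field.

The functional pieces (``equilibrium``, ``collide_srt``, ``collide_mrt``,
``stream``, ``macroscopics``) operate on numpy arrays shaped
``(19, ...)`` for direct use in tests and small periodic studies; the
production driver :func:`run_simulation` uses a fused numba kernel over the
fluid nodes only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(fn):
            return fn

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


__all__ = [
    "C",
    "W",
    "OPP",
    "CS2",
    "LatticeSpec",
    "VoxelLattice",
    "FlowField",
    "SimConfig",
    "mrt_matrix",
    "default_mrt_rates",
    "equilibrium",
    "macroscopics",
    "collide_srt",
    "collide_mrt",
    "stream",
    "guo_force_term",
    "voxelize",
    "run_simulation",
    "AIR_DENSITY",
]

#: Speed of sound squared in lattice units.
CS2 = 1.0 / 3.0

#: Air mass density used for the pressure unit conversion (kg/m^3, 20 C).
AIR_DENSITY = 1.204

#: D3Q19 discrete velocities: rest, 6 axis, 12 edge-diagonal directions.
C = np.array(
    [
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
    ],
    dtype=np.int64,
)

#: Quadrature weights: 1/3 rest, 1/18 axis, 1/36 diagonal.
W = np.array([1.0 / 3.0] + [1.0 / 18.0] * 6 + [1.0 / 36.0] * 12)

#: Index of the opposite velocity for each direction.
OPP = np.array(
    [int(np.flatnonzero((C == -c).all(axis=1))[0]) for c in C], dtype=np.int64
)


def mrt_matrix() -> np.ndarray:
    """The d'Humieres D3Q19 moment transform matrix (19 x 19).

    Rows are the standard polynomial moments: density, kinetic energy and its
    square, momentum and energy fluxes, diagonal/off-diagonal stress modes,
    and the third-order modes.
    """
    cx, cy, cz = C[:, 0].astype(float), C[:, 1].astype(float), C[:, 2].astype(float)
    c2 = cx**2 + cy**2 + cz**2
    rows = [
        np.ones(19),
        19.0 * c2 - 30.0,
        (21.0 * c2**2 - 53.0 * c2 + 24.0) / 2.0,
        cx,
        (5.0 * c2 - 9.0) * cx,
        cy,
        (5.0 * c2 - 9.0) * cy,
        cz,
        (5.0 * c2 - 9.0) * cz,
        3.0 * cx**2 - c2,
        (3.0 * c2 - 5.0) * (3.0 * cx**2 - c2),
        cy**2 - cz**2,
        (3.0 * c2 - 5.0) * (cy**2 - cz**2),
        cx * cy,
        cy * cz,
        cx * cz,
        (cy**2 - cz**2) * cx,
        (cz**2 - cx**2) * cy,
        (cx**2 - cy**2) * cz,
    ]
    return np.array(rows)


#: Moment indices relaxed at the shear-viscosity rate 1/tau.
_SHEAR_MOMENTS = (9, 11, 13, 14, 15)
#: Conserved moments (density and momentum); their rate is irrelevant.
_CONSERVED_MOMENTS = (0, 3, 5, 7)


def default_mrt_rates(tau: float, other: float = 1.2) -> np.ndarray:
    """Default MRT relaxation-rate vector for a given shear relaxation time.

    Conserved moments get rate 0, shear-viscosity moments 1/tau, all other
    (ghost/energy) moments a fixed stabilizing rate.
    """
    rates = np.full(19, other)
    rates[list(_CONSERVED_MOMENTS)] = 0.0
    rates[list(_SHEAR_MOMENTS)] = 1.0 / tau
    return rates


@dataclass
class LatticeSpec:
    """Discrete lattice plus physical conversion factors for one run."""

    dx: float                     # mm per lattice spacing
    dt: float                     # s per time step
    tau: float                    # SRT relaxation time (lattice units)
    mrt_rates: np.ndarray = field(default=None)  # type: ignore[assignment]
    velocity_set: np.ndarray = field(default_factory=lambda: C.copy())
    weights: np.ndarray = field(default_factory=lambda: W.copy())
    cs2: float = CS2

    def __post_init__(self) -> None:
        if self.tau <= 0.5:
            raise ValueError(f"tau must exceed 0.5 for stability; got {self.tau}")
        if self.mrt_rates is None:
            self.mrt_rates = default_mrt_rates(self.tau)
        self.mrt_rates = np.asarray(self.mrt_rates, float)
        w, c = self.weights, self.velocity_set.astype(float)
        if abs(w.sum() - 1.0) > 1e-14:
            raise ValueError("lattice weights must sum to 1")
        if np.abs(w @ c).max() > 1e-14:
            raise ValueError("first weight moment must vanish")
        second = np.einsum("i,ia,ib->ab", w, c, c)
        if np.abs(second - self.cs2 * np.eye(3)).max() > 1e-14:
            raise ValueError("second weight moment must equal cs2 * identity")

    @property
    def nu_lattice(self) -> float:
        return self.cs2 * (self.tau - 0.5)

    @property
    def nu_physical(self) -> float:
        """Kinematic viscosity in mm^2/s implied by (dx, dt, tau)."""
        return self.nu_lattice * self.dx**2 / self.dt


def equilibrium(rho: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Second-order Maxwellian equilibrium distributions.

    ``rho`` has shape ``(...)`` and ``u`` shape ``(3, ...)``; returns
    ``(19, ...)``.  Warns above |u| = 0.1 (compressibility error grows as
    Ma^2) and again above the hard 0.3 usability bound.
    """
    rho = np.asarray(rho, float)
    u = np.asarray(u, float)
    umag = np.sqrt((u**2).sum(axis=0)).max() if u.size else 0.0
    if umag > 0.3:
        warnings.warn(
            f"|u|={umag:.3f} lattice units exceeds 0.3; results unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    elif umag > 0.1:
        warnings.warn(
            f"|u|={umag:.3f} lattice units exceeds 0.1; compressibility error "
            "may be significant",
            RuntimeWarning,
            stacklevel=2,
        )
    cu = np.tensordot(C.astype(float), u, axes=(1, 0))      # (19, ...)
    usq = (u**2).sum(axis=0)
    shape = (19,) + (1,) * (rho.ndim)
    w = W.reshape(shape)
    return w * rho * (1.0 + 3.0 * cu + 4.5 * cu**2 - 1.5 * usq)


def macroscopics(
    f: np.ndarray, rho0: float = 1.0, force: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Density, velocity, and lattice pressure from distributions ``(19, ...)``.

    With a body force the velocity carries the conventional half-step
    correction ``u = (sum f_i c_i + F/2) / rho``.
    """
    rho = f.sum(axis=0)
    if np.any(rho <= 0):
        raise FloatingPointError("non-positive density: simulation unstable")
    mom = np.tensordot(C.astype(float).T, f, axes=(1, 0))   # (3, ...)
    if force is not None:
        mom = mom + 0.5 * np.asarray(force, float).reshape((3,) + (1,) * (rho.ndim))
    u = mom / rho
    p = CS2 * (rho - rho0)
    return rho, u, p


def guo_force_term(u: np.ndarray, force: np.ndarray) -> np.ndarray:
    """Guo et al. forcing source S_i for a constant body force (lattice units)."""
    force = np.asarray(force, float).reshape((3,) + (1,) * (u.ndim - 1))
    cu = np.tensordot(C.astype(float), u, axes=(1, 0))
    cf = np.tensordot(C.astype(float), force, axes=(1, 0))
    uf = (u * force).sum(axis=0)
    shape = (19,) + (1,) * (u.ndim - 1)
    w = W.reshape(shape)
    return w * (3.0 * (cf - uf) + 9.0 * cu * cf)


def collide_srt(f: np.ndarray, tau: float, force: np.ndarray | None = None) -> np.ndarray:
    """BGK collision: relax toward local equilibrium at a single rate 1/tau."""
    if tau <= 0.5:
        raise ValueError("tau must exceed 0.5")
    rho, u, _ = macroscopics(f, force=force)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        feq = equilibrium(rho, u)
    out = f - (f - feq) / tau
    if force is not None:
        out = out + (1.0 - 0.5 / tau) * guo_force_term(u, force)
    return out


def collide_mrt(
    f: np.ndarray, mrt_rates: np.ndarray, force: np.ndarray | None = None
) -> np.ndarray:
    """Multi-relaxation-time collision with per-moment rates.

    Rates must lie in (0, 2) except the conserved moments (density and
    momentum), whose rates are irrelevant and may be 0.  Setting every
    non-conserved rate to 1/tau reproduces :func:`collide_srt` exactly.
    """
    rates = np.asarray(mrt_rates, float)
    check = np.delete(rates, _CONSERVED_MOMENTS)
    if np.any((check <= 0) | (check >= 2)):
        raise ValueError("MRT rates must lie in (0, 2) for non-conserved moments")
    M = mrt_matrix()
    Cmat = np.linalg.solve(M, rates[:, None] * M)
    rho, u, _ = macroscopics(f, force=force)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        feq = equilibrium(rho, u)
    fneq = (f - feq).reshape(19, -1)
    out = f - (Cmat @ fneq).reshape(f.shape)
    if force is not None:
        S = guo_force_term(u, force)
        out = out + S - 0.5 * (Cmat @ S.reshape(19, -1)).reshape(f.shape)
    return out


def stream(f: np.ndarray, solid: np.ndarray | None = None) -> np.ndarray:
    """Advect each population one lattice link (periodic wrap at the borders).

    Where the pull source is a solid node the population is instead the
    node's own reversed post-collision population — halfway bounce-back,
    placing the no-slip wall midway along the cut link.
    """
    fnew = np.empty_like(f)
    axes = tuple(range(f.ndim - 1))
    for i in range(19):
        shift = tuple(int(s) for s in C[i][: len(axes)])
        fnew[i] = np.roll(f[i], shift, axis=axes)
        if solid is not None:
            from_solid = np.roll(solid, shift, axis=tuple(range(solid.ndim)))
            fnew[i][from_solid] = f[OPP[i]][from_solid]
    return fnew


# --------------------------------------------------------------------------
# voxelization
# --------------------------------------------------------------------------

SOLID, FLUID, INLET, OUTLET = 0, 1, 2, 3


@dataclass
class VoxelLattice:
    """Voxelized flow domain: occupancy grid plus grid-to-mm mapping.

    ``occupancy`` codes: 0 solid, 1 fluid, 2 inlet, 3 outlet.  Voxel
    ``(i, j, k)`` is centered at ``origin + (i+0.5, j+0.5, k+0.5) * dx`` mm.
    """

    occupancy: np.ndarray
    dx: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, np.uint8)
        self.origin = np.asarray(self.origin, float)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D grid")
        if self.dx <= 0:
            raise ValueError("dx must be positive")

    @property
    def fluid_mask(self) -> np.ndarray:
        return self.occupancy != SOLID

    @property
    def n_fluid(self) -> int:
        return int(self.fluid_mask.sum())

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates (mm) of voxel centers under ``mask`` (default fluid)."""
        mask = self.fluid_mask if mask is None else mask
        idx = np.argwhere(mask)
        return self.origin[None, :] + (idx + 0.5) * self.dx

    def classify_ends(self, axis: int = 2) -> None:
        """Label the first/last full fluid slab along ``axis`` as inlet/outlet.

        Slightly tilted end caps leave sliver sections beyond the last full
        slab; those are squared off (reverted to solid) so the inlet/outlet
        faces carry a complete cross-section.
        """
        occ = self.occupancy
        other = tuple(d for d in range(3) if d != axis)
        fluid_per_slab = (occ != SOLID).sum(axis=other)
        ks = np.flatnonzero(fluid_per_slab)
        if len(ks) == 0:
            raise ValueError("no fluid voxels to classify")
        # walk inward past sliver slabs (tilted end caps cut by the grid):
        # a slab is a sliver if it holds less than half its interior neighbor
        k0, k1 = int(ks[0]), int(ks[-1])
        while k0 < k1 and fluid_per_slab[k0] < 0.5 * fluid_per_slab[k0 + 1]:
            k0 += 1
        while k1 > k0 and fluid_per_slab[k1] < 0.5 * fluid_per_slab[k1 - 1]:
            k1 -= 1
        sl = [slice(None)] * 3
        for k in range(occ.shape[axis]):
            if k0 <= k <= k1:
                continue
            sl[axis] = k
            occ[tuple(sl)] = SOLID
        sl[axis] = k0
        occ[tuple(sl)][occ[tuple(sl)] != SOLID] = INLET
        sl[axis] = k1
        occ[tuple(sl)][occ[tuple(sl)] != SOLID] = OUTLET


def voxelize(surface, dx: float, pad: int = 2) -> VoxelLattice:
    """Voxelize a watertight surface: interior centers fluid, ends inlet/outlet.

    Slices the mesh with planes normal to +z at every voxel-center height and
    tests voxel centers against the closed section polygons; fluid voxels in
    the first (proximal, low z) and last occupied slabs are labeled inlet and
    outlet.  Warns when the narrowest section spans fewer than 10 voxels.
    """
    from shapely import contains_xy
    from shapely.ops import unary_union

    mesh = surface.mesh if hasattr(surface, "mesh") else surface
    if not mesh.is_watertight:
        raise ValueError("voxelize requires a watertight mesh")
    lo, hi = mesh.bounds
    origin = lo - pad * dx
    shape = np.ceil((hi - origin) / dx).astype(int) + pad
    nx, ny, nz = shape
    occ = np.zeros(shape, np.uint8)
    xs = origin[0] + (np.arange(nx) + 0.5) * dx
    ys = origin[1] + (np.arange(ny) + 0.5) * dx
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    counts: list[int] = []
    for k in range(nz):
        z = origin[2] + (k + 0.5) * dx
        if z <= lo[2] or z >= hi[2]:
            continue
        section = mesh.section(plane_origin=[0.0, 0.0, z], plane_normal=[0.0, 0.0, 1.0])
        if section is None:
            continue
        planar, T = section.to_2D()
        polys = planar.polygons_full
        if len(polys) == 0:
            continue
        union = unary_union(polys)
        Tinv = np.linalg.inv(T)
        pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z), np.ones(gx.size)])
        uv = (Tinv @ pts.T).T[:, :2]
        inside = contains_xy(union, uv[:, 0], uv[:, 1]).reshape(gx.shape)
        occ[:, :, k][inside] = FLUID
        n_in = int(inside.sum())
        if n_in:
            counts.append(n_in)
    lattice = VoxelLattice(occ, dx, origin)
    if lattice.n_fluid == 0:
        raise ValueError("voxelization produced no fluid voxels")
    # ignore sliver sections at tilted end caps when judging resolution
    full = [c for c in counts if c >= 0.5 * np.median(counts)]
    min_count = min(full) if full else min(counts)
    if 2.0 * np.sqrt(min_count / np.pi) < 10.0:
        warnings.warn(
            f"narrowest section spans ~{2*np.sqrt(min_count/np.pi):.1f} voxels "
            "(<10); refine dx for reliable flow",
            RuntimeWarning,
            stacklevel=2,
        )
    lattice.classify_ends(axis=2)
    return lattice


# --------------------------------------------------------------------------
# production driver
# --------------------------------------------------------------------------


@dataclass
class FlowField:
    """Macroscopic flow solution on the voxel grid with unit conversions.

    ``rho`` and ``u`` are time-averaged lattice-unit fields (NaN at solid
    voxels); ``pressure_pa()`` converts to model-scale pascals using the
    recorded dx/dt mapping and the density of air.  ``meta`` carries the
    complete unit bookkeeping (dx, dt, tau, Re, conversion factors,
    convergence history).
    """

    lattice: VoxelLattice
    rho: np.ndarray              # (nx, ny, nz), lattice units, time-averaged
    u: np.ndarray                # (3, nx, ny, nz), lattice units
    dx_mm: float
    dt_s: float
    rho0: float = 1.0
    meta: dict = field(default_factory=dict)
    snapshots: list = field(default_factory=list)

    @property
    def velocity_scale(self) -> float:
        """Physical metres per second per lattice velocity unit."""
        return (self.dx_mm * 1e-3) / self.dt_s

    @property
    def pressure_scale(self) -> float:
        """Pascals per lattice pressure unit (rho_air * C_u^2)."""
        return AIR_DENSITY * self.velocity_scale**2

    def pressure_pa(self) -> np.ndarray:
        return CS2 * (self.rho - self.rho0) * self.pressure_scale

    def velocity_ms(self) -> np.ndarray:
        return self.u * self.velocity_scale


@dataclass
class SimConfig:
    """Desk-scale run configuration.

    ``re_target`` sets the simulated Reynolds number by inflating the
    viscosity at fixed geometry; ``u_lat`` is the lattice-unit inlet speed
    that fixes the time step.  ``period_s`` maps the measured ~5 s breathing
    cycle into lattice time for the oscillatory mode.
    """

    re_target: float = 100.0
    u_lat: float = 0.04
    collision: str = "mrt"         # "srt" | "mrt"
    mrt_other_rate: float = 1.2
    ramp_steps: int = 500
    conv_tol: float = 1e-6
    conv_interval: int = 100
    avg_steps: int = 500
    max_steps: int = 60000
    period_s: float = 5.0
    n_cycles: int = 2
    n_snapshots: int = 2
    rho0: float = 1.0


def _build_node_tables(lattice: VoxelLattice):
    """Flatten the fluid nodes and build the pull-source neighbor table."""
    occ = lattice.occupancy
    mask = occ != SOLID
    idx = -np.ones(occ.shape, np.int64)
    coords = np.argwhere(mask)
    idx[mask] = np.arange(len(coords))
    nb = np.full((len(coords), 19), -1, np.int64)
    shape = np.array(occ.shape)
    for i in range(19):
        src = coords - C[i][None, :]
        ok = np.all((src >= 0) & (src < shape[None, :]), axis=1)
        si = src[ok]
        nb[ok, i] = idx[si[:, 0], si[:, 1], si[:, 2]]
    return coords, idx, nb


@njit(cache=True)
def _lbm_steps(f, fbuf, nb, opp, Cmat, w, cx, cy, cz, n_sub):
    """Fused collide (general relaxation matrix) + stream for n_sub steps."""
    n_nodes = f.shape[0]
    fneq = np.empty(19)
    for _ in range(n_sub):
        for nd in range(n_nodes):
            rho = 0.0
            ux = 0.0
            uy = 0.0
            uz = 0.0
            for i in range(19):
                fi = f[nd, i]
                rho += fi
                ux += fi * cx[i]
                uy += fi * cy[i]
                uz += fi * cz[i]
            ux /= rho
            uy /= rho
            uz /= rho
            usq = ux * ux + uy * uy + uz * uz
            for i in range(19):
                cu = cx[i] * ux + cy[i] * uy + cz[i] * uz
                feq = w[i] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
                fneq[i] = f[nd, i] - feq
            for i in range(19):
                acc = 0.0
                for j in range(19):
                    acc += Cmat[i, j] * fneq[j]
                f[nd, i] -= acc
        for nd in range(n_nodes):
            for i in range(19):
                src = nb[nd, i]
                if src >= 0:
                    fbuf[nd, i] = f[src, i]
                else:
                    fbuf[nd, i] = f[nd, opp[i]]
        f[:, :] = fbuf[:, :]


def _node_equilibrium(rho: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Equilibrium for flat node arrays: rho (n,), u (n, 3) -> (n, 19)."""
    cu = u @ C.T.astype(float)
    usq = (u**2).sum(axis=1)
    return W[None, :] * rho[:, None] * (
        1.0 + 3.0 * cu + 4.5 * cu**2 - 1.5 * usq[:, None]
    )


def _apply_inout(f, inlet_ids, inlet_nb, u_in_vec, outlet_ids, outlet_nb, rho0):
    """Non-equilibrium-extrapolation velocity inlet and density outlet."""
    for ids, nbr, mode in ((inlet_ids, inlet_nb, "u"), (outlet_ids, outlet_nb, "p")):
        if len(ids) == 0:
            continue
        fn = f[nbr]
        rho_n = fn.sum(axis=1)
        u_n = (fn @ C.astype(float)) / rho_n[:, None]
        feq_n = _node_equilibrium(rho_n, u_n)
        if mode == "u":
            u_b = np.broadcast_to(u_in_vec, (len(ids), 3))
            feq_b = _node_equilibrium(rho_n, u_b)
        else:
            feq_b = _node_equilibrium(np.full(len(ids), rho0), u_n)
        f[ids] = feq_b + (fn - feq_n)


def derive_units(
    lattice: VoxelLattice, inflow_lpm: float, config: SimConfig
) -> tuple[LatticeSpec, dict]:
    """Fix (dt, tau) from (dx, target Re, lattice inlet speed) and log them.

    The physical inlet speed follows from the flow rate and the voxelized
    inlet area; viscosity is chosen so the Reynolds number based on the
    equivalent inlet diameter equals ``re_target``.
    """
    if inflow_lpm <= 0:
        raise ValueError("inflow must be positive")
    n_inlet = int((lattice.occupancy == INLET).sum())
    if n_inlet == 0:
        raise ValueError("lattice has no inlet voxels")
    area_mm2 = n_inlet * lattice.dx**2
    q_mm3_s = inflow_lpm * 1e6 / 60.0
    u_phys = q_mm3_s / area_mm2                    # mm/s
    d_h = 2.0 * np.sqrt(area_mm2 / np.pi)          # mm, equivalent diameter
    nu_sim = u_phys * d_h / config.re_target       # mm^2/s (inflated viscosity)
    dt = config.u_lat * lattice.dx / u_phys        # s
    nu_lat = nu_sim * dt / lattice.dx**2
    tau = 3.0 * nu_lat + 0.5
    if tau <= 0.502:
        warnings.warn(
            f"tau={tau:.4f} is marginal; increase u_lat or coarsen dx",
            RuntimeWarning,
            stacklevel=2,
        )
    spec = LatticeSpec(dx=lattice.dx, dt=dt, tau=tau)
    meta = {
        "inflow_lpm": inflow_lpm,
        "inlet_area_mm2": area_mm2,
        "u_inlet_phys_mm_s": u_phys,
        "u_inlet_phys_m_s": u_phys * 1e-3,
        "hydraulic_diameter_mm": d_h,
        "nu_sim_mm2_s": nu_sim,
        "reynolds": u_phys * d_h / nu_sim,
        "dx_mm": lattice.dx,
        "dt_s": dt,
        "tau": tau,
        "u_lat": config.u_lat,
        "collision": config.collision,
        "desk_scale_note": (
            "viscosity inflated to reach the target Reynolds number at desk "
            "scale; physiological-Re direct simulation is out of scope"
        ),
    }
    return spec, meta


def run_simulation(
    lattice: VoxelLattice,
    inflow_lpm: float,
    mode: str = "steady",
    config: SimConfig | None = None,
) -> FlowField:
    """Drive flow through a classified lattice and return the averaged field.

    The inlet imposes a plug velocity matching the requested volumetric flow,
    ramped over the first ``ramp_steps`` steps; the outlet holds the
    reference density.  Steady mode iterates until the relative change of the
    velocity field over ``conv_interval`` steps drops below ``conv_tol``
    (or ``max_steps``), then time-averages ``avg_steps`` further steps.
    Oscillatory mode modulates the inflow over the mapped ~5 s breathing
    period and averages the final cycle.
    """
    if mode not in ("steady", "oscillatory"):
        raise ValueError(f"mode must be 'steady' or 'oscillatory', got {mode!r}")
    config = config or SimConfig()
    spec, meta = derive_units(lattice, inflow_lpm, config)
    if config.collision == "srt":
        Cmat = np.eye(19) / spec.tau
    elif config.collision == "mrt":
        rates = default_mrt_rates(spec.tau, config.mrt_other_rate)
        M = mrt_matrix()
        Cmat = np.linalg.solve(M, rates[:, None] * M)
    else:
        raise ValueError(f"unknown collision operator {config.collision!r}")

    coords, idx, nb = _build_node_tables(lattice)
    occ_flat = lattice.occupancy[coords[:, 0], coords[:, 1], coords[:, 2]]
    inlet_ids = np.flatnonzero(occ_flat == INLET)
    outlet_ids = np.flatnonzero(occ_flat == OUTLET)
    # interior neighbor one node along +z (inlet) / -z (outlet)
    inlet_nb = idx[coords[inlet_ids, 0], coords[inlet_ids, 1], coords[inlet_ids, 2] + 1]
    outlet_nb = idx[coords[outlet_ids, 0], coords[outlet_ids, 1], coords[outlet_ids, 2] - 1]
    # staircase corners can leave boundary cells without an interior neighbor;
    # treat those as wall
    for ids_arr, nb_arr in ((inlet_ids, inlet_nb), (outlet_ids, outlet_nb)):
        orphan = nb_arr < 0
        if orphan.any():
            oc = coords[ids_arr[orphan]]
            lattice.occupancy[oc[:, 0], oc[:, 1], oc[:, 2]] = SOLID
    if np.any(inlet_nb < 0) or np.any(outlet_nb < 0):
        coords, idx, nb = _build_node_tables(lattice)
        occ_flat = lattice.occupancy[coords[:, 0], coords[:, 1], coords[:, 2]]
        inlet_ids = np.flatnonzero(occ_flat == INLET)
        outlet_ids = np.flatnonzero(occ_flat == OUTLET)
        inlet_nb = idx[coords[inlet_ids, 0], coords[inlet_ids, 1], coords[inlet_ids, 2] + 1]
        outlet_nb = idx[coords[outlet_ids, 0], coords[outlet_ids, 1], coords[outlet_ids, 2] - 1]
        if np.any(inlet_nb < 0) or np.any(outlet_nb < 0) or len(inlet_ids) == 0:
            raise ValueError("inlet/outlet voxels lack interior neighbors")

    n = len(coords)
    f = np.tile(W, (n, 1))
    fbuf = np.empty_like(f)
    cx = C[:, 0].astype(float)
    cy = C[:, 1].astype(float)
    cz = C[:, 2].astype(float)

    u_prev = None
    history: list[tuple[int, float]] = []
    converged = False
    step = 0

    def inlet_speed(k: int) -> float:
        ramp = min(1.0, (k + 1) / max(config.ramp_steps, 1))
        if mode == "steady":
            return config.u_lat * ramp
        t_lat = k * spec.dt
        osc = 0.5 * (1.0 - np.cos(2.0 * np.pi * t_lat / config.period_s))
        return config.u_lat * ramp * osc

    def check_stable(uvec: np.ndarray) -> None:
        umax = np.sqrt((uvec**2).sum(axis=1)).max()
        if not np.isfinite(umax) or umax > 0.4:
            raise FloatingPointError(
                f"instability detected (|u|max={umax:.3f} lattice units); "
                "increase tau (coarser dx or larger u_lat) or reduce inflow"
            )

    def node_velocity() -> np.ndarray:
        rho = f.sum(axis=1)
        return (f @ C.astype(float)) / rho[:, None]

    if mode == "steady":
        while step < config.max_steps and not converged:
            for _ in range(config.conv_interval):
                _lbm_steps(f, fbuf, nb, OPP, Cmat, W, cx, cy, cz, 1)
                _apply_inout(
                    f,
                    inlet_ids,
                    inlet_nb,
                    np.array([0.0, 0.0, inlet_speed(step)]),
                    outlet_ids,
                    outlet_nb,
                    config.rho0,
                )
                step += 1
            uvec = node_velocity()
            check_stable(uvec)
            if u_prev is not None and step > config.ramp_steps:
                num = np.linalg.norm(uvec - u_prev)
                den = np.linalg.norm(uvec) + 1e-30
                history.append((step, num / den))
                converged = num / den < config.conv_tol
            u_prev = uvec
        if not converged:
            warnings.warn(
                f"steady run hit max_steps={config.max_steps} before reaching "
                f"conv_tol={config.conv_tol}; last residual "
                f"{history[-1][1] if history else float('nan'):.2e}",
                RuntimeWarning,
                stacklevel=2,
            )
        n_avg = config.avg_steps
    else:
        period_steps = max(int(round(config.period_s / spec.dt)), 1)
        warm = period_steps * max(config.n_cycles - 1, 1)
        for k in range(warm):
            _lbm_steps(f, fbuf, nb, OPP, Cmat, W, cx, cy, cz, 1)
            _apply_inout(
                f,
                inlet_ids,
                inlet_nb,
                np.array([0.0, 0.0, inlet_speed(k)]),
                outlet_ids,
                outlet_nb,
                config.rho0,
            )
            if (k + 1) % 500 == 0:
                check_stable(node_velocity())
        step = warm
        n_avg = period_steps

    rho_acc = np.zeros(n)
    u_acc = np.zeros((n, 3))
    snap_every = max(n_avg // max(config.n_snapshots, 1), 1)
    snapshots = []
    for k in range(n_avg):
        _lbm_steps(f, fbuf, nb, OPP, Cmat, W, cx, cy, cz, 1)
        _apply_inout(
            f,
            inlet_ids,
            inlet_nb,
            np.array([0.0, 0.0, inlet_speed(step + k)]),
            outlet_ids,
            outlet_nb,
            config.rho0,
        )
        rho = f.sum(axis=1)
        uvec = (f @ C.astype(float)) / rho[:, None]
        rho_acc += rho
        u_acc += uvec
        if (k + 1) % snap_every == 0 and len(snapshots) < config.n_snapshots:
            snapshots.append((step + k + 1, uvec.copy()))
    check_stable(u_acc / n_avg)
    rho_mean = rho_acc / n_avg
    u_mean = u_acc / n_avg

    shape = lattice.occupancy.shape
    rho_grid = np.full(shape, np.nan)
    u_grid = np.full((3,) + shape, np.nan)
    ii, jj, kk = coords[:, 0], coords[:, 1], coords[:, 2]
    rho_grid[ii, jj, kk] = rho_mean
    for a in range(3):
        u_grid[a, ii, jj, kk] = u_mean[:, a]

    meta.update(
        {
            "mode": mode,
            "steps_total": step + n_avg,
            "converged": bool(converged) if mode == "steady" else None,
            "convergence_history": history,
            "avg_steps": n_avg,
            "velocity_scale_m_s": (lattice.dx * 1e-3) / spec.dt,
            "pressure_scale_pa": AIR_DENSITY * ((lattice.dx * 1e-3) / spec.dt) ** 2,
        }
    )
    field_snapshots = [(s, u.copy()) for s, u in snapshots]
    return FlowField(
        lattice=lattice,
        rho=rho_grid,
        u=u_grid,
        dx_mm=lattice.dx,
        dt_s=spec.dt,
        rho0=config.rho0,
        meta=meta,
        snapshots=field_snapshots,
    )
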