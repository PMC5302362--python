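"""Buoyancy-driven laminar flow and conjugate heat transfer on a voxel grid.

The model: incompressible flow of the syrup with the Boussinesq
approximation (density constant except in the buoyancy term, linearised in
temperature), temperature-dependent viscosity, conductivity and heat
capacity, conduction in the solid particles, and one shared temperature
field.  The can wall is held at the process-medium temperature (infinite
external heat-transfer coefficient, negligible wall resistance), with
no-slip everywhere on wall and particle surfaces.

Discretisation: uniform staggered (MAC) grid over the voxelized scene.
Advection of momentum and energy is first-order upwind; diffusion is
explicit and stability-limited; buoyancy is explicit; incompressibility is
enforced each step by a pressure projection solved with a prefactorised
sparse direct solver, so the discrete divergence is zero to round-off.
The energy update is written in flux form (one flux per face, harmonic-mean
face conductivity across material interfaces, Dirichlet wall flux over the
half-cell distance), which makes the scheme exactly conservative: the change
of Σ ρCp·V·T over a step equals the net wall conductive heat times dt.

Mid-plane symmetry (half domain, z ≥ 0) is supported: the mid-plane is a
zero-normal-flow, zero-gradient plane realised by reflecting ghost layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import VoxelScene
from .lethality import LethalityField
from .properties import PropertyModel, thermal_expansion

__all__ = [
    "SolverConfig",
    "ProcessPhase",
    "FlowState",
    "Discretization",
    "StabilityError",
    "ConvergenceError",
    "select_dt",
    "momentum_step",
    "energy_step",
    "run_phase",
    "PhaseResult",
    "Probe",
    "cell_speed",
    "divergence",
]


class StabilityError(RuntimeError):
    """Time step exceeds an explicit stability limit."""


class ConvergenceError(RuntimeError):
    """Pressure projection failed to reach the requested residual."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls of the time stepper."""

    courant_target: float = 0.5
    dt_cap: float = 0.5              # s; never exceeded
    diffusion_safety: float = 0.45   # fraction of the explicit diffusive limit
    pressure_tolerance: float = 1e-6  # relative divergence residual
    max_pressure_iterations: int = 500
    buoyancy_reference_T: Optional[float] = None  # None → phase mean
    flow_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.courant_target <= 1:
            raise ValueError("courant_target must lie in (0, 1]")
        if self.dt_cap <= 0:
            raise ValueError("dt_cap must be positive")


@dataclass(frozen=True)
class ProcessPhase:
    """One constant-medium-temperature leg of the process schedule."""

    medium_temperature: float  # °C
    duration: float            # s

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be non-negative")


@dataclass
class FlowState:
    """Staggered velocities, pressure and temperature at one instant."""

    u: np.ndarray  # (nx+1, ny, nz) x-face velocities, m/s
    v: np.ndarray  # (nx, ny+1, nz)
    w: np.ndarray  # (nx, ny, nz+1)
    T: np.ndarray  # (nx, ny, nz) cell temperatures, °C
    pressure: np.ndarray  # (nx, ny, nz) fluid pressure, Pa (0 elsewhere)
    time: float = 0.0

    @classmethod
    def initial(cls, scene: VoxelScene, T0: float) -> "FlowState":
        nx, ny, nz = scene.dims
        return cls(
            u=np.zeros((nx + 1, ny, nz)),
            v=np.zeros((nx, ny + 1, nz)),
            w=np.zeros((nx, ny, nz + 1)),
            T=np.full((nx, ny, nz), float(T0)),
            pressure=np.zeros((nx, ny, nz)),
            time=0.0,
        )

    def copy(self) -> "FlowState":
        return FlowState(
            self.u.copy(), self.v.copy(), self.w.copy(),
            self.T.copy(), self.pressure.copy(), self.time,
        )


def _pad_face(arr: np.ndarray, symmetry: bool, reflect_zlow: bool) -> np.ndarray:
    """Zero-pad a face array; optionally reflect the low-z ghost (symmetry)."""
    out = np.pad(arr, 1)
    if symmetry and reflect_zlow:
        out[:, :, 0] = out[:, :, 1]  # mirror of the first interior layer
    return out


class Discretization:
    """Static per-scene structures: masks, face activity, pressure factor."""

    def __init__(self, scene: VoxelScene, model: PropertyModel):
        self.scene = scene
        self.model = model
        self.h = scene.spacing
        nx, ny, nz = scene.dims
        self.dims = (nx, ny, nz)
        fluid = scene.fluid
        self.fluid = fluid
        self.solid = scene.solid
        self.interior = scene.interior

        fpad = np.pad(fluid, 1, constant_values=False)
        # Active (momentum-carrying) faces: fluid on both sides.  The pad is
        # False beyond the domain, so the symmetry mid-plane face (low z) is
        # inactive — zero normal flow through the plane.
        self.active_u = fpad[:-1, 1:-1, 1:-1] & fpad[1:, 1:-1, 1:-1]
        self.active_v = fpad[1:-1, :-1, 1:-1] & fpad[1:-1, 1:, 1:-1]
        self.active_w = fpad[1:-1, 1:-1, :-1] & fpad[1:-1, 1:-1, 1:]

        ipad = np.pad(self.interior, 1, constant_values=False)
        if scene.symmetry:
            ipad[:, :, 0] = ipad[:, :, 1]
        self.interior_pad = ipad

        # Constant solid property fields.
        peach = model.peach
        self.k_solid = peach.conductivity * self.solid
        self.rhocp_solid = peach.volumetric_heat_capacity * self.solid

        self._build_pressure_solver()

    # -- pressure projection -------------------------------------------------

    def _build_pressure_solver(self) -> None:
        fluid = self.fluid
        nf = int(fluid.sum())
        self.n_fluid = nf
        if nf == 0:
            self._lu = None
            return
        idx = -np.ones(self.dims, dtype=np.int64)
        idx[fluid] = np.arange(nf)

        rows: List[np.ndarray] = []
        cols: List[np.ndarray] = []
        for axis, active in ((0, self.active_u), (1, self.active_v),
                             (2, self.active_w)):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(0, -1)
            sl_hi[axis] = slice(1, None)
            interior_faces = [slice(None)] * 3
            interior_faces[axis] = slice(1, -1)
            act = active[tuple(interior_faces)]
            c1 = idx[tuple(sl_lo)][act]
            c2 = idx[tuple(sl_hi)][act]
            rows.append(c1)
            cols.append(c2)
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        # Negative Laplacian: degree on the diagonal, −1 across active faces.
        deg = np.bincount(np.concatenate([r, c]), minlength=nf).astype(float)
        data = np.concatenate([deg, -np.ones(r.size), -np.ones(r.size)])
        ij_r = np.concatenate([np.arange(nf), r, c])
        ij_c = np.concatenate([np.arange(nf), c, r])
        M = sp.csr_matrix((data, (ij_r, ij_c)), shape=(nf, nf))

        # Pin one cell per connected fluid component (pure-Neumann null space).
        lab, ncomp = ndi.label(fluid, structure=ndi.generate_binary_structure(3, 1))
        pinned = []
        flat_lab = lab[fluid]
        for comp in range(1, ncomp + 1):
            pinned.append(int(np.argmax(flat_lab == comp)))
        self._pinned = np.array(pinned, dtype=np.int64)
        M = M.tolil()
        for p in pinned:
            M.rows[p] = [p]
            M.data[p] = [1.0]
        self._lu = spla.splu(M.tocsc())
        self._fluid_index = idx

    def solve_pressure(self, rhs_grid: np.ndarray) -> np.ndarray:
        """Solve ∇²φ = rhs on fluid cells (Neumann walls); returns φ grid."""
        b = -self.h**2 * rhs_grid[self.fluid]
        b[self._pinned] = 0.0
        phi_flat = self._lu.solve(b)
        phi = np.zeros(self.dims)
        phi[self.fluid] = phi_flat
        return phi

    # -- per-step property fields -------------------------------------------

    def conductivity_field(self, T: np.ndarray) -> np.ndarray:
        k = self.model.syrup["conductivity"].evaluate(T, check=False)
        return np.where(self.fluid, k, self.k_solid)

    def heat_capacity_field(self, T: np.ndarray) -> np.ndarray:
        rho = self.model.syrup["density"].evaluate(T, check=False)
        cp = self.model.syrup["specific_heat"].evaluate(T, check=False)
        out = np.where(self.fluid, rho * cp, self.rhocp_solid)
        return np.where(self.interior, out, 1.0)


def divergence(state: FlowState, h: float) -> np.ndarray:
    """Discrete per-cell velocity divergence (1/s)."""
    return (
        np.diff(state.u, axis=0) + np.diff(state.v, axis=1)
        + np.diff(state.w, axis=2)
    ) / h


def cell_speed(state: FlowState) -> np.ndarray:
    """Cell-centred speed magnitude from face velocities."""
    uc = 0.5 * (state.u[:-1] + state.u[1:])
    vc = 0.5 * (state.v[:, :-1] + state.v[:, 1:])
    wc = 0.5 * (state.w[:, :, :-1] + state.w[:, :, 1:])
    return np.sqrt(uc**2 + vc**2 + wc**2)


def _max_cell_face_speed_sum(state: FlowState) -> float:
    """max over cells of Σ_axes max(|face speeds|) — advective CFL scale."""
    su = np.maximum(np.abs(state.u[:-1]), np.abs(state.u[1:]))
    sv = np.maximum(np.abs(state.v[:, :-1]), np.abs(state.v[:, 1:]))
    sw = np.maximum(np.abs(state.w[:, :, :-1]), np.abs(state.w[:, :, 1:]))
    total = su + sv + sw
    return float(total.max()) if total.size else 0.0


def select_dt(
    state: FlowState,
    scene: VoxelScene,
    model: PropertyModel,
    config: SolverConfig,
) -> float:
    """Adaptive time step: cap, advective Courant limit, diffusive limits."""
    h = scene.spacing
    dt = config.dt_cap

    smax = _max_cell_face_speed_sum(state)
    if smax > 0:
        dt = min(dt, config.courant_target * h / smax)

    Tf = state.T[scene.fluid]
    if Tf.size:
        t_lo, t_hi = float(Tf.min()), float(Tf.max())
        ends = np.array([t_lo, t_hi])
        rho = model.syrup["density"].evaluate(ends, check=False)
        if config.flow_enabled:
            mu = model.syrup["viscosity"].evaluate(ends, check=False)
            nu_max = float(np.max(mu / rho))
            if nu_max > 0:
                dt = min(dt, config.diffusion_safety * h**2 / (6.0 * nu_max))
        cp = model.syrup["specific_heat"].evaluate(ends, check=False)
        k = model.syrup["conductivity"].evaluate(ends, check=False)
        alpha_max = float(np.max(k / (rho * cp)))
    else:
        alpha_max = 0.0
    if scene.solid.any():
        alpha_max = max(alpha_max, model.peach.diffusivity)
    if alpha_max > 0:
        # factor 12 (not 6): wall faces act over a half-cell distance
        dt = min(dt, 0.9 * h**2 / (12.0 * alpha_max))
    return dt


def momentum_step(
    state: FlowState,
    scene: VoxelScene,
    model: PropertyModel,
    dt: float,
    disc: Discretization,
    config: SolverConfig,
    beta: float,
    rho0: float,
    T_ref_buoy: float,
) -> None:
    """Explicit upwind advection + diffusion + buoyancy, then projection."""
    h = disc.h
    nx, ny, nz = disc.dims
    sym = scene.symmetry
    g = model.gravity_magnitude
    ghat = np.asarray(scene.gravity_unit)
    mu_poly = model.syrup["viscosity"]

    Tp = np.pad(state.T, 1, mode="edge")

    up = _pad_face(state.u, sym, True)
    vp = _pad_face(state.v, sym, True)
    wp = _pad_face(state.w, sym, False)

    def component_rhs(comp: int) -> np.ndarray:
        if comp == 0:
            c = state.u
            cp_ = up
            # face-neighbour values (zero / reflected beyond boundaries)
            xm, xp_ = cp_[:-2, 1:-1, 1:-1], cp_[2:, 1:-1, 1:-1]
            ym, yp_ = cp_[1:-1, :-2, 1:-1], cp_[1:-1, 2:, 1:-1]
            zm, zp_ = cp_[1:-1, 1:-1, :-2], cp_[1:-1, 1:-1, 2:]
            a1 = c
            a2 = 0.25 * (vp[0:nx + 1, 1:ny + 1, 1:nz + 1]
                         + vp[0:nx + 1, 2:ny + 2, 1:nz + 1]
                         + vp[1:nx + 2, 1:ny + 1, 1:nz + 1]
                         + vp[1:nx + 2, 2:ny + 2, 1:nz + 1])
            a3 = 0.25 * (wp[0:nx + 1, 1:ny + 1, 1:nz + 1]
                         + wp[0:nx + 1, 1:ny + 1, 2:nz + 2]
                         + wp[1:nx + 2, 1:ny + 1, 1:nz + 1]
                         + wp[1:nx + 2, 1:ny + 1, 2:nz + 2])
            Tface = 0.5 * (Tp[0:nx + 1, 1:-1, 1:-1] + Tp[1:nx + 2, 1:-1, 1:-1])
        elif comp == 1:
            c = state.v
            cp_ = vp
            xm, xp_ = cp_[:-2, 1:-1, 1:-1], cp_[2:, 1:-1, 1:-1]
            ym, yp_ = cp_[1:-1, :-2, 1:-1], cp_[1:-1, 2:, 1:-1]
            zm, zp_ = cp_[1:-1, 1:-1, :-2], cp_[1:-1, 1:-1, 2:]
            a1 = 0.25 * (up[1:nx + 1, 0:ny + 1, 1:nz + 1]
                         + up[1:nx + 1, 1:ny + 2, 1:nz + 1]
                         + up[2:nx + 2, 0:ny + 1, 1:nz + 1]
                         + up[2:nx + 2, 1:ny + 2, 1:nz + 1])
            a2 = c
            a3 = 0.25 * (wp[1:nx + 1, 0:ny + 1, 1:nz + 1]
                         + wp[1:nx + 1, 0:ny + 1, 2:nz + 2]
                         + wp[1:nx + 1, 1:ny + 2, 1:nz + 1]
                         + wp[1:nx + 1, 1:ny + 2, 2:nz + 2])
            Tface = 0.5 * (Tp[1:-1, 0:ny + 1, 1:-1] + Tp[1:-1, 1:ny + 2, 1:-1])
        else:
            c = state.w
            cp_ = wp
            xm, xp_ = cp_[:-2, 1:-1, 1:-1], cp_[2:, 1:-1, 1:-1]
            ym, yp_ = cp_[1:-1, :-2, 1:-1], cp_[1:-1, 2:, 1:-1]
            zm, zp_ = cp_[1:-1, 1:-1, :-2], cp_[1:-1, 1:-1, 2:]
            a1 = 0.25 * (up[1:nx + 1, 1:ny + 1, 0:nz + 1]
                         + up[1:nx + 1, 1:ny + 1, 1:nz + 2]
                         + up[2:nx + 2, 1:ny + 1, 0:nz + 1]
                         + up[2:nx + 2, 1:ny + 1, 1:nz + 2])
            a2 = 0.25 * (vp[1:nx + 1, 1:ny + 1, 0:nz + 1]
                         + vp[1:nx + 1, 2:ny + 2, 0:nz + 1]
                         + vp[1:nx + 1, 1:ny + 1, 1:nz + 2]
                         + vp[1:nx + 1, 2:ny + 2, 1:nz + 2])
            a3 = c
            Tface = 0.5 * (Tp[1:-1, 1:-1, 0:nz + 1] + Tp[1:-1, 1:-1, 1:nz + 2])

        adv = (
            a1 * np.where(a1 > 0, c - xm, xp_ - c)
            + a2 * np.where(a2 > 0, c - ym, yp_ - c)
            + a3 * np.where(a3 > 0, c - zm, zp_ - c)
        ) / h
        lap = (xm + xp_ + ym + yp_ + zm + zp_ - 6.0 * c) / h**2
        nu = mu_poly.evaluate(Tface, check=False) / rho0
        rhs = -adv + nu * lap
        if ghat[comp] != 0.0:
            rhs = rhs - g * ghat[comp] * beta * (Tface - T_ref_buoy)
        return rhs

    if config.flow_enabled and disc.n_fluid:
        ru = component_rhs(0)
        rv = component_rhs(1)
        rw = component_rhs(2)
        state.u += dt * ru
        state.v += dt * rv
        state.w += dt * rw
    state.u[~disc.active_u] = 0.0
    state.v[~disc.active_v] = 0.0
    state.w[~disc.active_w] = 0.0

    if not (config.flow_enabled and disc.n_fluid):
        return

    ustar_max = max(float(np.abs(state.u).max()), float(np.abs(state.v).max()),
                    float(np.abs(state.w).max()), 1e-12)
    div = divergence(state, h)
    phi = disc.solve_pressure(np.where(disc.fluid, div, 0.0) / dt)
    gx = (phi[1:] - phi[:-1]) / h
    gy = (phi[:, 1:] - phi[:, :-1]) / h
    gz = (phi[:, :, 1:] - phi[:, :, :-1]) / h
    au = disc.active_u[1:-1]
    av = disc.active_v[:, 1:-1]
    aw = disc.active_w[:, :, 1:-1]
    state.u[1:-1][au] -= dt * gx[au]
    state.v[:, 1:-1][av] -= dt * gy[av]
    state.w[:, :, 1:-1][aw] -= dt * gz[aw]
    state.pressure = rho0 * phi

    resid = np.abs(divergence(state, h)[disc.fluid])
    scale = ustar_max / h  # round-off scales with the pre-projection field
    if resid.size and float(resid.max()) > config.pressure_tolerance * scale:
        raise ConvergenceError(
            f"projection residual {float(resid.max()):.3e} exceeds "
            f"{config.pressure_tolerance:.1e} × {scale:.3e}"
        )


def energy_step(
    state: FlowState,
    scene: VoxelScene,
    model: PropertyModel,
    dt: float,
    wall_T: float,
    disc: Discretization,
    diagnostics: Optional[dict] = None,
) -> None:
    """Conservative finite-volume energy update (upwind advection +
    harmonic-mean conduction + Dirichlet wall), in place.

    If ``diagnostics`` is a dict it receives ``boundary_heat_W`` (net
    conductive heat entering through the can wall) and ``heat_capacity``
    (the per-cell ρCp field frozen at the start of the step), which together
    state the exact discrete energy balance of the step.
    """
    h = disc.h
    nx, ny, nz = disc.dims
    sym = scene.symmetry
    A = h * h
    V = h**3
    T = state.T
    interior = disc.interior

    kc = disc.conductivity_field(T)
    rhocp = disc.heat_capacity_field(T)

    # Stability guard (advective part is guarded in select_dt).
    # Explicit conduction limit per cell: rhoCp·V / Σ coef·A.
    Twork = np.where(interior, T, wall_T)
    Tw = np.pad(Twork, 1, constant_values=wall_T)
    kp = np.pad(np.where(interior, kc, 0.0), 1)
    if sym:
        Tw[:, :, 0] = Tw[:, :, 1]
        kp[:, :, 0] = kp[:, :, 1]
    ip = disc.interior_pad

    g_adv = np.where(disc.fluid, rhocp * T, 0.0)
    gp = np.pad(g_adv, 1)

    net = np.zeros(disc.dims)
    coef_sum = np.zeros(disc.dims)
    q_wall = 0.0
    faces = (
        (0, state.u, (slice(None), slice(1, -1), slice(1, -1))),
        (1, state.v, (slice(1, -1), slice(None), slice(1, -1))),
        (2, state.w, (slice(1, -1), slice(1, -1), slice(None))),
    )
    for axis, vel, face_region in faces:
        lo = [slice(1, -1)] * 3
        hi = [slice(1, -1)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)

        i1, i2 = ip[lo], ip[hi]
        k1, k2 = kp[lo], kp[hi]
        both = i1 & i2
        wall = i1 ^ i2
        denom = np.where(k1 + k2 > 0, k1 + k2, 1.0)
        coef = np.where(both, 2.0 * k1 * k2 / denom,
                        np.where(wall, 2.0 * (k1 + k2), 0.0)) / h
        F = coef * A * (Tw[hi] - Tw[lo])

        # advective face flux of ρCp·T, upwinded (active faces only: vel=0
        # elsewhere, and g_adv vanishes outside the fluid)
        G = vel * A * np.where(vel > 0, gp[lo], gp[hi])

        flux = F - G
        dlo = [slice(None)] * 3
        dhi = [slice(None)] * 3
        dlo[axis] = slice(0, -1)
        dhi[axis] = slice(1, None)
        net += flux[tuple(dhi)] - flux[tuple(dlo)]
        coef_sum += coef[tuple(dhi)] * A + coef[tuple(dlo)] * A

        q_wall += float(F[wall & i1].sum()) - float(F[wall & i2].sum())

    limit = rhocp[interior] * V / np.maximum(coef_sum[interior], 1e-300)
    if dt > float(limit.min()) * (1.0 + 1e-12):
        raise StabilityError(
            f"dt={dt:.4g} s exceeds the explicit conduction limit "
            f"{float(limit.min()):.4g} s"
        )

    dT = dt * net / (rhocp * V)
    state.T = np.where(interior, T + dT, T)
    if diagnostics is not None:
        diagnostics["boundary_heat_W"] = q_wall
        diagnostics["heat_capacity"] = rhocp


@dataclass(frozen=True)
class Probe:
    """Named temperature probe at a fixed location (mm from can centre)."""

    probe_id: str
    x_mm: float
    y_mm: float
    z_mm: float

    def voxel_index(self, scene: VoxelScene) -> Tuple[int, int, int]:
        pos = np.array([self.x_mm, self.y_mm, self.z_mm]) / 1000.0
        idx = np.floor((pos - np.asarray(scene.origin)) / scene.spacing).astype(int)
        idx = np.clip(idx, 0, np.asarray(scene.dims) - 1)
        return tuple(int(i) for i in idx)


@dataclass
class PhaseResult:
    """Time series gathered while integrating one process phase."""

    times: np.ndarray                 # s, one entry per step
    max_speed: np.ndarray             # m/s, max fluid cell speed per step
    probe_temperatures: Dict[str, np.ndarray]
    end_state: FlowState

    def max_speed_at(self, t: float) -> float:
        """Max fluid speed at the first recorded time ≥ t (s)."""
        i = int(np.searchsorted(self.times, t - 1e-9))
        i = min(i, len(self.times) - 1)
        return float(self.max_speed[i])


def run_phase(
    state: FlowState,
    scene: VoxelScene,
    model: PropertyModel,
    phase: ProcessPhase,
    config: SolverConfig = SolverConfig(),
    probes: Sequence[Probe] = (),
    lethality_field: Optional[LethalityField] = None,
    disc: Optional[Discretization] = None,
    step_callback: Optional[Callable[[FlowState], None]] = None,
) -> PhaseResult:
    """Advance the coupled solver through one process phase, in place.

    Momentum and energy are stepped with a shared adaptive dt until the phase
    duration is met exactly (final step truncated).  A ``lethality_field``
    registered here is advanced one trapezoid per step over every voxel.
    """
    if disc is None:
        disc = Discretization(scene, model)
    wall_T = phase.medium_temperature

    if config.buoyancy_reference_T is not None:
        T_ref_buoy = config.buoyancy_reference_T
    else:
        start_T = float(state.T[disc.fluid].mean()) if disc.n_fluid else wall_T
        T_ref_buoy = 0.5 * (start_T + wall_T)
    if config.flow_enabled and disc.n_fluid and model.gravity_magnitude > 0:
        beta = float(thermal_expansion(model, T_ref_buoy, check=False))
    else:
        beta = 0.0
    rho0 = float(model.syrup["density"].evaluate(T_ref_buoy, check=False))

    if lethality_field is not None and lethality_field.last_time is None:
        lethality_field.start(state.T, state.time)

    probe_idx = {p.probe_id: p.voxel_index(scene) for p in probes}
    times: List[float] = []
    speeds: List[float] = []
    probe_series: Dict[str, List[float]] = {pid: [] for pid in probe_idx}

    t_end = state.time + phase.duration
    fluid = disc.fluid
    while state.time < t_end - 1e-9:
        dt = min(select_dt(state, scene, model, config), t_end - state.time)
        if config.flow_enabled and disc.n_fluid:
            momentum_step(state, scene, model, dt, disc, config,
                          beta, rho0, T_ref_buoy)
        energy_step(state, scene, model, dt, wall_T, disc)
        state.time += dt

        if lethality_field is not None:
            lethality_field.accumulate(state.T, state.time)
        times.append(state.time)
        if disc.n_fluid:
            speeds.append(float(cell_speed(state)[fluid].max()))
        else:
            speeds.append(0.0)
        for pid, idx in probe_idx.items():
            probe_series[pid].append(float(state.T[idx]))
        if step_callback is not None:
            step_callback(state)

    return PhaseResult(
        times=np.asarray(times),
        max_speed=np.asarray(speeds),
        probe_temperatures={k: np.asarray(v) for k, v in probe_series.items()},
        end_state=state,
    )
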