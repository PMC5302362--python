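"""Process lethality (F value) accumulation and critical-point location.

The F value of a time–temperature history T(t) is the equivalent time, in
minutes at a reference temperature, producing the same microbial destruction:

    F = ∫ 10^((T(t) − T_ref) / z) dt

with the classical first-order kinetics of thermobacteriology.  Defaults
target *Clostridium butyricum* in acid food: z = 11.5 °C, T_ref = 90 °C,
D(90 °C) = 1.1 min, six decimal reductions, hence a target F of 6.6 min.

The field accumulator mirrors the solver loop: every time step appends one
trapezoid per voxel, so the accumulated field equals ``integrate_f`` applied
to each voxel's sampled history exactly (same rule, same points).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .geometry import VoxelScene

__all__ = [
    "LethalityParams",
    "LethalityField",
    "CriticalPointReport",
    "lethal_rate",
    "integrate_f",
    "ramp_f_exact",
    "target_f",
    "locate_critical",
    "slowest_heating_point",
    "interior_solid_mask",
]


@dataclass(frozen=True)
class LethalityParams:
    """First-order thermal-death kinetics."""

    T_ref: float = 90.0       # °C
    z: float = 11.5           # °C per decade of D
    D_ref: float = 1.1        # min at T_ref
    log_reductions: float = 6.0

    def __post_init__(self) -> None:
        if self.z <= 0 or self.D_ref <= 0:
            raise ValueError("z and D_ref must be positive")


def lethal_rate(T, params: LethalityParams = LethalityParams()):
    """Instantaneous lethal rate 10^((T − T_ref)/z); dimensionless."""
    return 10.0 ** ((np.asarray(T, dtype=float) - params.T_ref) / params.z)


def integrate_f(
    times_s, temperatures, params: LethalityParams = LethalityParams()
) -> float:
    """Trapezoidal F value (minutes) of a sampled time–temperature profile.

    ``times_s`` are seconds, strictly increasing; temperatures in °C.
    """
    t = np.asarray(times_s, dtype=float)
    T = np.asarray(temperatures, dtype=float)
    if t.shape != T.shape or t.ndim != 1 or t.size < 2:
        raise ValueError("need matching 1-D time/temperature arrays (>= 2 samples)")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time stamps must be strictly increasing")
    if not np.all(np.isfinite(T)):
        raise ValueError("temperatures must be finite")
    return float(np.trapezoid(lethal_rate(T, params), t) / 60.0)


def ramp_f_exact(
    T1: float, T2: float, duration_min: float,
    params: LethalityParams = LethalityParams(),
) -> float:
    """Closed-form F (minutes) of a linear temperature ramp T1 → T2.

    Antiderivative of the lethal rate along the ramp; reduces to
    ``duration · 10^((T1 − T_ref)/z)`` for a constant segment.
    """
    if duration_min < 0:
        raise ValueError("duration must be non-negative")
    r1 = float(lethal_rate(T1, params))
    if T1 == T2:
        return duration_min * r1
    r2 = float(lethal_rate(T2, params))
    return duration_min * params.z / (np.log(10.0) * (T2 - T1)) * (r2 - r1)


def target_f(params: LethalityParams = LethalityParams()) -> float:
    """Target process F (minutes) = log reductions × D_ref."""
    return params.log_reductions * params.D_ref


@dataclass
class LethalityField:
    """Per-voxel accumulated F (minutes), advanced step by step."""

    shape: Tuple[int, ...]
    params: LethalityParams = field(default_factory=LethalityParams)
    F: np.ndarray = field(init=False)
    last_time: Optional[float] = field(init=False, default=None)
    _last_rate: Optional[np.ndarray] = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.F = np.zeros(self.shape, dtype=float)

    def start(self, temperatures: np.ndarray, t_now: float) -> None:
        """Record the initial temperature field at ``t_now`` seconds."""
        self._last_rate = np.asarray(lethal_rate(temperatures, self.params))
        self.last_time = float(t_now)

    def accumulate(self, temperatures: np.ndarray, t_now: float) -> None:
        """Add one trapezoid per voxel from ``last_time`` to ``t_now``."""
        if self.last_time is None or self._last_rate is None:
            raise ValueError("call start() with the initial field first")
        if t_now <= self.last_time:
            raise ValueError("time must advance monotonically")
        rate = np.asarray(lethal_rate(temperatures, self.params))
        dt_min = (t_now - self.last_time) / 60.0
        self.F += 0.5 * (self._last_rate + rate) * dt_min
        self._last_rate = rate
        self.last_time = float(t_now)


@dataclass(frozen=True)
class CriticalPointReport:
    """Least-processed voxel of a finished run."""

    location_mm: Tuple[float, float, float]
    F_min: float
    particle_id: int
    index: Tuple[int, int, int]


def _argmin_masked(values: np.ndarray, mask: np.ndarray) -> Tuple[int, int, int]:
    """First (lexicographically smallest index) minimum within ``mask``."""
    if not mask.any():
        raise ValueError("empty restriction set")
    work = np.where(mask, values, np.inf)
    flat = int(np.argmin(work))  # C order → lexicographic (x, y, z) tie-break
    return tuple(int(i) for i in np.unravel_index(flat, values.shape))


def interior_solid_mask(scene: VoxelScene) -> np.ndarray:
    """Solid voxels none of whose 6-neighbours is fluid (particle interior).

    Under mid-plane symmetry the low-z neighbour across the plane is the
    mirror image, i.e. solid whenever the voxel itself is solid.
    """
    solid = scene.solid
    fluid = scene.fluid
    pad = np.pad(fluid, 1, constant_values=False)
    if scene.symmetry:
        pad[:, :, 0] = pad[:, :, 1]  # reflect across the mid-plane
    near_fluid = (
        pad[:-2, 1:-1, 1:-1] | pad[2:, 1:-1, 1:-1]
        | pad[1:-1, :-2, 1:-1] | pad[1:-1, 2:, 1:-1]
        | pad[1:-1, 1:-1, :-2] | pad[1:-1, 1:-1, 2:]
    )
    return solid & ~near_fluid


def locate_critical(
    field: LethalityField,
    scene: VoxelScene,
    restrict_to: str = "particles",
) -> CriticalPointReport:
    """Locate the voxel with minimum accumulated F.

    ``restrict_to='particles'`` searches solid voxels only (the particles);
    ``'everywhere'`` searches all interior voxels.  Ties break toward the
    lexicographically smallest (x, y, z) index.
    """
    if restrict_to == "particles":
        mask = scene.solid
    elif restrict_to == "everywhere":
        mask = scene.interior
    else:
        raise ValueError("restrict_to must be 'particles' or 'everywhere'")
    idx = _argmin_masked(field.F, mask)
    return CriticalPointReport(
        location_mm=scene.index_to_mm(idx),
        F_min=float(field.F[idx]),
        particle_id=int(scene.particle_id[idx]),
        index=idx,
    )


def per_particle_min_f(
    field: LethalityField, scene: VoxelScene, interior_only: bool = False
) -> Tuple[float, ...]:
    """Minimum F per particle, ordered by particle id.

    ``interior_only`` restricts to voxels not adjacent to fluid, mirroring
    reports that quote minima at the interior of the particles.
    """
    n = int(scene.particle_id.max()) + 1
    if n <= 0:
        return ()
    base = interior_solid_mask(scene) if interior_only else scene.solid
    out = []
    for pid in range(n):
        mask = base & (scene.particle_id == pid)
        if not mask.any():  # fall back to all voxels of the particle
            mask = scene.particle_id == pid
        out.append(float(field.F[mask].min()))
    return tuple(out)


def slowest_heating_point(
    temperatures: np.ndarray, scene: VoxelScene
) -> Tuple[Tuple[float, float, float], Tuple[int, int, int]]:
    """Coldest solid voxel of an end-of-heating snapshot (location mm, index)."""
    idx = _argmin_masked(np.asarray(temperatures, dtype=float), scene.solid)
    return scene.index_to_mm(idx), idx


def slowest_cooling_point(
    temperatures: np.ndarray, scene: VoxelScene
) -> Tuple[Tuple[float, float, float], Tuple[int, int, int]]:
    """Hottest solid voxel of an end-of-cooling snapshot (location mm, index)."""
    idx = _argmin_masked(-np.asarray(temperatures, dtype=float), scene.solid)
    return scene.index_to_mm(idx), idx
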