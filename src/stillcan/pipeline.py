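"""End-to-end orientation study: heat, cool, accumulate lethality, compare.

One case = build the scene for an orientation, voxelize, run the heating
phase (default 20 min at 100 °C from 20 °C) then the cooling phase (default
20 min at 20 °C) with per-step F accumulation over both phases, and collect
the summary quantities: maximum fluid speeds 30 s into each phase, the F
range over the particles, per-particle minimum F (interior of the particles),
the critical point, and the slowest-heating / slowest-cooling points.

The whole pipeline is deterministic — identical configurations produce
bit-identical reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .geometry import CanSpec, PeachHalfSpec, Scene, VoxelScene, build_case, voxelize
from .lethality import (
    CriticalPointReport,
    LethalityField,
    LethalityParams,
    locate_critical,
    per_particle_min_f,
    slowest_cooling_point,
    slowest_heating_point,
)
from .properties import PropertyModel, default_property_model
from .solver import (
    Discretization,
    FlowState,
    PhaseResult,
    Probe,
    ProcessPhase,
    SolverConfig,
    run_phase,
)

__all__ = [
    "CaseConfig",
    "CaseReport",
    "StudyReport",
    "ComparabilityError",
    "run_case",
    "run_study",
    "compare_cases",
]


class ComparabilityError(ValueError):
    """Cross-case comparison attempted on mismatched configurations."""


@dataclass(frozen=True)
class CaseConfig:
    """Everything needed to simulate one orientation case."""

    case_name: str = "upward"
    spacing: float = 0.0025          # m
    symmetry: bool = False           # mid-plane half domain
    heating: ProcessPhase = field(
        default_factory=lambda: ProcessPhase(100.0, 1200.0))
    cooling: ProcessPhase = field(
        default_factory=lambda: ProcessPhase(20.0, 1200.0))
    initial_T: float = 20.0          # °C
    solver: SolverConfig = field(default_factory=SolverConfig)
    lethality: LethalityParams = field(default_factory=LethalityParams)
    probes: Tuple[Probe, ...] = ()
    can: Optional[CanSpec] = None
    peach: Optional[PeachHalfSpec] = None

    def __post_init__(self) -> None:
        if self.heating.duration <= 0 or self.cooling.duration <= 0:
            raise ValueError("phase durations must be strictly positive")


@dataclass
class CaseReport:
    """Summary of one simulated case (speeds m/s, F in min, locations mm)."""

    case_name: str
    spacing: float
    max_speed_heating_30s: float
    max_speed_cooling_30s: float
    per_particle_min_F: Tuple[float, ...]           # interior of each particle
    per_particle_min_F_all: Tuple[float, ...]       # including surface voxels
    F_min: float                                    # over all solid voxels
    F_max: float
    F_min_end_heating: float
    critical_point: CriticalPointReport
    slowest_heating_mm: Tuple[float, float, float]
    slowest_heating_index: Tuple[int, int, int]
    slowest_cooling_mm: Tuple[float, float, float]
    T_end_heating_at_critical: float                # °C
    target_F: float
    heating_series: PhaseResult
    cooling_series: PhaseResult
    probes: Tuple[Probe, ...] = ()
    # final fields for optional VTK export (not part of the CSV row)
    voxels: Optional[VoxelScene] = None
    final_temperature: Optional[np.ndarray] = None
    F_field: Optional[np.ndarray] = None

    def to_row(self) -> Dict[str, object]:
        cp = self.critical_point
        row: Dict[str, object] = {
            "case": self.case_name,
            "spacing_mm": self.spacing * 1000.0,
            "max_speed_heating_30s_cm_s": self.max_speed_heating_30s * 100.0,
            "max_speed_cooling_30s_cm_s": self.max_speed_cooling_30s * 100.0,
            "F_min_min": self.F_min,
            "F_max_min": self.F_max,
            "F_min_end_heating_min": self.F_min_end_heating,
            "critical_x_mm": cp.location_mm[0],
            "critical_y_mm": cp.location_mm[1],
            "critical_z_mm": cp.location_mm[2],
            "critical_F_min": cp.F_min,
            "critical_particle": cp.particle_id,
            "slowest_heating_x_mm": self.slowest_heating_mm[0],
            "slowest_heating_y_mm": self.slowest_heating_mm[1],
            "slowest_heating_z_mm": self.slowest_heating_mm[2],
            "slowest_cooling_x_mm": self.slowest_cooling_mm[0],
            "slowest_cooling_y_mm": self.slowest_cooling_mm[1],
            "slowest_cooling_z_mm": self.slowest_cooling_mm[2],
            "T_end_heating_at_critical_C": self.T_end_heating_at_critical,
            "target_F_min": self.target_F,
        }
        for i, f in enumerate(self.per_particle_min_F):
            row[f"particle{i}_min_F_min"] = f
        return row


def run_case(
    config: CaseConfig, model: Optional[PropertyModel] = None
) -> CaseReport:
    """Simulate one orientation case end to end and summarise it."""
    model = model or default_property_model()
    scene = build_case(config.case_name, can=config.can, peach=config.peach)
    vox = voxelize(scene, config.spacing, symmetry=config.symmetry)
    disc = Discretization(vox, model)
    state = FlowState.initial(vox, config.initial_T)
    leth = LethalityField(vox.dims, config.lethality)

    heating = run_phase(state, vox, model, config.heating, config.solver,
                        probes=config.probes, lethality_field=leth, disc=disc)
    T_end_heating = state.T.copy()
    F_end_heating = leth.F.copy()
    cooling = run_phase(state, vox, model, config.cooling, config.solver,
                        probes=config.probes, lethality_field=leth, disc=disc)

    critical = locate_critical(leth, vox, restrict_to="particles")
    slow_heat_mm, slow_heat_idx = slowest_heating_point(T_end_heating, vox)
    slow_cool_mm, _ = slowest_cooling_point(state.T, vox)
    solid = vox.solid

    from .lethality import target_f  # local import avoids a cycle at module load

    return CaseReport(
        case_name=config.case_name,
        spacing=config.spacing,
        max_speed_heating_30s=heating.max_speed_at(30.0),
        max_speed_cooling_30s=cooling.max_speed_at(config.heating.duration + 30.0),
        per_particle_min_F=per_particle_min_f(leth, vox, interior_only=True),
        per_particle_min_F_all=per_particle_min_f(leth, vox, interior_only=False),
        F_min=float(leth.F[solid].min()),
        F_max=float(leth.F[solid].max()),
        F_min_end_heating=float(F_end_heating[solid].min()),
        critical_point=critical,
        slowest_heating_mm=slow_heat_mm,
        slowest_heating_index=slow_heat_idx,
        slowest_cooling_mm=slow_cool_mm,
        T_end_heating_at_critical=float(T_end_heating[critical.index]),
        target_F=target_f(config.lethality),
        heating_series=heating,
        cooling_series=cooling,
        probes=config.probes,
        voxels=vox,
        final_temperature=state.T.copy(),
        F_field=leth.F.copy(),
    )


def run_study(
    base_config: Optional[CaseConfig] = None,
    model: Optional[PropertyModel] = None,
    cases: Sequence[str] = ("upward", "downward", "sideward"),
) -> Dict[str, CaseReport]:
    """Run all requested orientation cases with one shared configuration."""
    base = base_config or CaseConfig()
    return {
        name: run_case(replace(base, case_name=name), model=model)
        for name in cases
    }


@dataclass(frozen=True)
class StudyReport:
    """Cross-case orderings the orientation study is expected to show."""

    critical_F: Dict[str, float]
    critical_F_ordering_holds: bool       # upward < downward < sideward
    upward_heats_slowest_at_critical: bool
    per_particle_spread: Dict[str, float]
    sideward_tightest_spread: bool
    upward_critical_in_bottom_half: bool
    downward_critical_in_bottom_half: bool
    upward_coincidence_distance_mm: float  # critical vs slowest-heating point


def _critical_in_bottom(report: CaseReport) -> bool:
    """True when the critical point sits in the bottom peach half.

    For the upright-can cases particle 0 is the half nearest the can bottom.
    """
    return report.critical_point.particle_id == 0


def compare_cases(reports: Dict[str, CaseReport]) -> StudyReport:
    """Evaluate the cross-case orderings from three case reports."""
    needed = {"upward", "downward", "sideward"}
    if set(reports) != needed:
        raise ComparabilityError(f"need exactly the cases {sorted(needed)}")
    spacings = {r.spacing for r in reports.values()}
    if len(spacings) != 1:
        raise ComparabilityError("cases were run at different resolutions")
    for name, r in reports.items():
        if r.case_name != name:
            raise ComparabilityError("report labels do not match their keys")

    crit = {name: r.critical_point.F_min for name, r in reports.items()}
    ordering = crit["upward"] < crit["downward"] < crit["sideward"]

    t_end_heat = {
        name: r.T_end_heating_at_critical for name, r in reports.items()
    }
    upward_slowest = t_end_heat["upward"] == min(t_end_heat.values())

    spread = {
        name: max(r.per_particle_min_F) - min(r.per_particle_min_F)
        for name, r in reports.items()
    }
    tightest = spread["sideward"] == min(spread.values())

    up = reports["upward"]
    d_mm = float(
        np.linalg.norm(
            np.asarray(up.critical_point.location_mm)
            - np.asarray(up.slowest_heating_mm)
        )
    )

    return StudyReport(
        critical_F=crit,
        critical_F_ordering_holds=ordering,
        upward_heats_slowest_at_critical=upward_slowest,
        per_particle_spread=spread,
        sideward_tightest_spread=tightest,
        upward_critical_in_bottom_half=_critical_in_bottom(reports["upward"]),
        downward_critical_in_bottom_half=_critical_in_bottom(reports["downward"]),
        upward_coincidence_distance_mm=d_mm,
    )
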