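"""Shared fixtures: property models, miniature scenes, and the (expensive)
three-case orientation study, run once per session at desk-scale resolution."""

from __future__ import annotations

import numpy as np
import pytest

from stillcan.fixtures import mini_scene
from stillcan.geometry import voxelize
from stillcan.pipeline import CaseConfig, run_case
from stillcan.properties import default_property_model
from stillcan.solver import (
    Discretization,
    FlowState,
    ProcessPhase,
    SolverConfig,
    run_phase,
)

#: Desk-scale study conditions: the process schedule of the study (20 min at
#: 100 °C, then 20 min at 20 °C, from 20 °C) on a 2.5 mm grid using the
#: mid-plane symmetry half-domain.
STUDY_SPACING = 0.0025
STUDY_CONFIG = dict(spacing=STUDY_SPACING, symmetry=True)


@pytest.fixture(scope="session")
def study_spacing():
    return STUDY_SPACING


@pytest.fixture(scope="session")
def make_planted_report():
    """Factory for CaseReports with planted lethality values."""
    from stillcan.lethality import CriticalPointReport
    from stillcan.pipeline import CaseReport
    from stillcan.solver import PhaseResult

    def _make(case_name, per_particle, crit_particle=0, T_end_heat=95.0,
              spacing=STUDY_SPACING):
        empty = PhaseResult(
            times=np.array([]), max_speed=np.array([]),
            probe_temperatures={}, end_state=None,
        )
        f_min = min(per_particle)
        return CaseReport(
            case_name=case_name,
            spacing=spacing,
            max_speed_heating_30s=0.02,
            max_speed_cooling_30s=0.02,
            per_particle_min_F=tuple(per_particle),
            per_particle_min_F_all=tuple(per_particle),
            F_min=f_min,
            F_max=max(per_particle) + 50.0,
            F_min_end_heating=f_min / 2,
            critical_point=CriticalPointReport(
                location_mm=(0.0, -40.0, 0.0), F_min=f_min,
                particle_id=crit_particle, index=(1, 2, 3),
            ),
            slowest_heating_mm=(0.0, -40.0, 0.0),
            slowest_heating_index=(1, 2, 3),
            slowest_cooling_mm=(0.0, 10.0, 0.0),
            T_end_heating_at_critical=T_end_heat,
            target_F=6.6,
            heating_series=empty,
            cooling_series=empty,
        )

    return _make


@pytest.fixture(scope="session")
def model():
    return default_property_model()


@pytest.fixture(scope="session")
def mini_peach_vox():
    """Miniature can with one peach half, voxelized at 1.5 mm, full domain."""
    return voxelize(mini_scene("single_peach_half"), 0.0015, symmetry=False)


@pytest.fixture(scope="session")
def mini_heating_run(model, mini_peach_vox):
    """60 s of heating at 100 °C on the miniature peach scene.

    Shared by the maximum-principle, mid-plane-symmetry and divergence
    checks; returns (scene, final state, phase result, discretization).
    """
    vox = mini_peach_vox
    disc = Discretization(vox, model)
    state = FlowState.initial(vox, 20.0)
    result = run_phase(
        state, vox, model, ProcessPhase(100.0, 60.0), SolverConfig(), disc=disc
    )
    return vox, state, result, disc


@pytest.fixture(scope="session")
def study_reports(model):
    """The full three-orientation study at desk scale (heavy, run once)."""
    reports = {}
    for case in ("upward", "downward", "sideward"):
        reports[case] = run_case(
            CaseConfig(case_name=case, **STUDY_CONFIG), model=model
        )
    return reports
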