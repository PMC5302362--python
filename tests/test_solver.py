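"""Flow/energy solver verification: stability limits, conservation,
conduction-limit oracles, symmetry and mirror equivalence."""

from dataclasses import replace

import numpy as np
import pytest

from stillcan.fixtures import AnalyticConductionSpec, analytic_temperature, mini_scene
from stillcan.geometry import SOLID, CanSpec, VoxelScene, build_case, voxelize
from stillcan.properties import default_property_model
from stillcan.solver import (
    Discretization,
    FlowState,
    Probe,
    ProcessPhase,
    SolverConfig,
    StabilityError,
    cell_speed,
    divergence,
    energy_step,
    run_phase,
    select_dt,
)


def make_box_scene(dims=(12, 16, 10), spacing=0.002) -> VoxelScene:
    """All-solid rectangular block with Dirichlet walls on every face.

    The wall sits exactly on the outer voxel faces, so the discrete problem
    matches a slab-product conduction problem with no stair-step error.
    """
    nx, ny, nz = dims
    labels = np.full(dims, SOLID, dtype=np.int8)
    return VoxelScene(
        spacing=spacing,
        dims=dims,
        origin=(-nx * spacing / 2, -ny * spacing / 2, -nz * spacing / 2),
        labels=labels,
        particle_id=np.zeros(dims, dtype=np.int16),
        gravity_unit=(0.0, -1.0, 0.0),
        case_name="box",
        symmetry=False,
        can=CanSpec(diameter=nx * spacing, height=ny * spacing),
    )


class TestSelectDt:
    def test_zero_velocity_hits_cap(self, model):
        vox = voxelize(mini_scene("empty_can"), 0.003)
        state = FlowState.initial(vox, 60.0)
        assert select_dt(state, vox, model, SolverConfig()) == 0.5

    @pytest.mark.parametrize("spacing,expected", [(0.0025, 0.05), (0.00125, 0.025)])
    def test_advective_limit_scales_with_spacing(self, model, spacing, expected):
        vox = voxelize(build_case("upward"), spacing)
        state = FlowState.initial(vox, 60.0)
        fluid = vox.fluid
        # one active x-face between two fluid cells near the wall
        idx = np.argwhere(fluid[:-1] & fluid[1:])[0]
        state.u[idx[0] + 1, idx[1], idx[2]] = 0.025
        dt = select_dt(state, vox, model, SolverConfig())
        assert dt == pytest.approx(expected, rel=1e-12)


class TestEnergyStep:
    def test_equilibrium_is_fixed_point(self, model):
        vox = voxelize(mini_scene("single_peach_half"), 0.0015)
        disc = Discretization(vox, model)
        state = FlowState.initial(vox, 100.0)
        before = state.T.copy()
        energy_step(state, vox, model, 0.5, 100.0, disc)
        assert np.array_equal(state.T, before)

    def test_exceeding_conduction_limit_raises(self, model):
        vox = voxelize(mini_scene("single_peach_half"), 0.0015)
        disc = Discretization(vox, model)
        state = FlowState.initial(vox, 20.0)
        with pytest.raises(StabilityError):
            energy_step(state, vox, model, 10.0, 100.0, disc)

    def test_enthalpy_balance_exact_per_step(self, model):
        """Σ ρCp·V·ΔT over a step equals the net wall heat times dt."""
        vox = voxelize(mini_scene("single_peach_half"), 0.0015)
        disc = Discretization(vox, model)
        state = FlowState.initial(vox, 20.0)
        run_phase(state, vox, model, ProcessPhase(100.0, 10.0),
                  SolverConfig(), disc=disc)
        for _ in range(3):
            before = state.T.copy()
            diag = {}
            dt = select_dt(state, vox, model, SolverConfig())
            energy_step(state, vox, model, dt, 100.0, disc, diagnostics=diag)
            cap = diag["heat_capacity"]
            dH = float(
                (cap * vox.cell_volume * (state.T - before))[vox.interior].sum()
            )
            expected = diag["boundary_heat_W"] * dt
            assert dH == pytest.approx(expected, rel=1e-8)


class TestConductionLimit:
    def test_box_matches_slab_product_series(self, model):
        """Buoyancy-free all-solid block vs the exact 3-slab product series."""
        vox = make_box_scene()
        disc = Discretization(vox, model)
        state = FlowState.initial(vox, 20.0)
        config = SolverConfig(flow_enabled=False)
        alpha = model.peach.diffusivity
        half = [d * vox.spacing / 2 for d in vox.dims]
        center_idx = (vox.dims[0] // 2, vox.dims[1] // 2, vox.dims[2] // 2)
        center = [vox.axis_centers(a)[center_idx[a]] for a in range(3)]

        checkpoints = (60.0, 150.0, 300.0)
        t_prev = 0.0
        for t in checkpoints:
            run_phase(state, vox, model, ProcessPhase(100.0, t - t_prev),
                      config, disc=disc)
            t_prev = t
            theta = 1.0
            for axis in range(3):
                spec = AnalyticConductionSpec(
                    geometry="slab", half_thickness=half[axis],
                    diffusivity=alpha, initial_T=20.0, wall_T=100.0,
                )
                Ts = analytic_temperature(spec, (center[axis], 0.0, 0.0), t)
                theta *= (Ts - 100.0) / (20.0 - 100.0)
            expected = 100.0 + (20.0 - 100.0) * theta
            assert state.T[center_idx] == pytest.approx(expected, abs=0.8)


class TestMomentum:
    def test_uniform_temperature_keeps_fluid_at_rest(self, model):
        vox = voxelize(mini_scene("single_peach_half"), 0.0015)
        state = FlowState.initial(vox, 60.0)
        # medium at the initial temperature: no driving force at all
        run_phase(state, vox, model, ProcessPhase(60.0, 10.0), SolverConfig())
        assert float(cell_speed(state).max()) < 1e-9

    def test_divergence_free_and_bounded(self, model, mini_heating_run):
        vox, state, _, disc = mini_heating_run
        resid = np.abs(divergence(state, vox.spacing)[vox.fluid]).max()
        scale = max(float(np.abs(state.u).max()), 1e-12) / vox.spacing
        assert resid <= SolverConfig().pressure_tolerance * scale
        T = state.T[vox.interior]
        assert T.min() >= 20.0 - 1e-6 and T.max() <= 100.0 + 1e-6

    def test_mid_plane_symmetry_preserved(self):
        """A z-symmetric scene stays mirror-symmetric about the mid-plane.

        Run in a mildly buoyant steady regime: at full gravity the plume
        pattern is physically unstable and chaotically amplifies solver
        round-off, which would test the flow's stability, not the scheme's
        symmetry.
        """
        m = default_property_model(gravity_magnitude=0.3)
        vox = voxelize(mini_scene("single_peach_half"), 0.0015)
        state = FlowState.initial(vox, 20.0)
        run_phase(state, vox, m, ProcessPhase(100.0, 60.0), SolverConfig())
        assert np.allclose(state.T, state.T[:, :, ::-1], atol=1e-6 * 80.0)
        scale_u = max(float(np.abs(state.u).max()), 1e-12)
        assert np.allclose(state.w, -state.w[:, :, ::-1], atol=1e-6 * scale_u)
        assert np.allclose(state.u, state.u[:, :, ::-1], atol=1e-6 * scale_u)


class TestMirrorEquivalence:
    """Upward scene with inverted gravity == mirrored downward scene.

    The first check runs a few lockstep steps at full gravity and demands
    machine-level agreement (exercises the scene/gravity wiring).  The
    second integrates 60 s in a mildly buoyant regime, where the flow is
    steady and solver round-off is not chaotically amplified, and demands
    1e-6 agreement end to end.
    """

    @staticmethod
    def _mirrored_pair(h, gravity_magnitude=None):
        from stillcan.properties import default_property_model

        model = (default_property_model() if gravity_magnitude is None
                 else default_property_model(gravity_magnitude=gravity_magnitude))
        scene_up = build_case("upward")
        vox_flip = voxelize(replace(scene_up, gravity_unit=(0.0, 1.0, 0.0)), h)
        vox_down = voxelize(build_case("downward"), h)
        assert np.array_equal(vox_flip.labels[:, ::-1, :], vox_down.labels)
        return model, vox_flip, vox_down

    def test_lockstep_steps_mirror_to_machine_precision(self):
        from stillcan.properties import thermal_expansion
        from stillcan.solver import momentum_step

        model, vox_flip, vox_down = self._mirrored_pair(0.00375)
        d1 = Discretization(vox_flip, model)
        d2 = Discretization(vox_down, model)
        s1 = FlowState.initial(vox_flip, 20.0)
        s2 = FlowState.initial(vox_down, 20.0)
        cfg = SolverConfig()
        T_ref = 60.0
        beta = float(thermal_expansion(model, T_ref))
        rho0 = float(model.syrup["density"].evaluate(T_ref))
        for _ in range(5):
            dt = min(select_dt(s1, vox_flip, model, cfg),
                     select_dt(s2, vox_down, model, cfg))
            momentum_step(s1, vox_flip, model, dt, d1, cfg, beta, rho0, T_ref)
            momentum_step(s2, vox_down, model, dt, d2, cfg, beta, rho0, T_ref)
            energy_step(s1, vox_flip, model, dt, 100.0, d1)
            energy_step(s2, vox_down, model, dt, 100.0, d2)
        umax = max(float(np.abs(s2.u).max()), 1e-12)
        assert np.allclose(s1.T[:, ::-1, :], s2.T, atol=1e-9 * 80.0)
        assert np.allclose(s1.u[:, ::-1, :], s2.u, atol=1e-9 * umax)
        assert np.allclose(s1.v[:, ::-1, :], -s2.v, atol=1e-9 * umax)
        assert np.allclose(s1.w[:, ::-1, :], s2.w, atol=1e-9 * umax)

    def test_60s_equivalence_in_steady_regime(self):
        model, vox_flip, vox_down = self._mirrored_pair(0.00375,
                                                        gravity_magnitude=0.3)
        s1 = FlowState.initial(vox_flip, 20.0)
        run_phase(s1, vox_flip, model, ProcessPhase(100.0, 60.0), SolverConfig())
        s2 = FlowState.initial(vox_down, 20.0)
        run_phase(s2, vox_down, model, ProcessPhase(100.0, 60.0), SolverConfig())

        umax = max(float(np.abs(s2.u).max()), 1e-12)
        assert np.allclose(s1.T[:, ::-1, :], s2.T, atol=1e-6 * 80.0)
        assert np.allclose(s1.u[:, ::-1, :], s2.u, atol=1e-6 * umax)
        assert np.allclose(s1.v[:, ::-1, :], -s2.v, atol=1e-6 * umax)
        assert np.allclose(s1.w[:, ::-1, :], s2.w, atol=1e-6 * umax)


class TestGridRefinement:
    def test_probe_consistent_between_3mm_and_2mm(self, model):
        """Solid-interior probe after 5 min of heating moves < 2 °C with grid."""
        temps = {}
        for h in (0.003, 0.002):
            vox = voxelize(mini_scene("single_peach_half"), h)
            state = FlowState.initial(vox, 20.0)
            run_phase(state, vox, model, ProcessPhase(100.0, 300.0),
                      SolverConfig())
            idx = Probe("p", 0.0, -1.5, 0.0).voxel_index(vox)
            temps[h] = float(state.T[idx])
        assert abs(temps[0.003] - temps[0.002]) < 2.0


class TestRunPhase:
    def test_zero_duration_returns_unchanged(self, model):
        vox = voxelize(mini_scene("empty_can"), 0.0015)
        state = FlowState.initial(vox, 20.0)
        before = state.T.copy()
        result = run_phase(state, vox, model, ProcessPhase(100.0, 0.0),
                           SolverConfig())
        assert np.array_equal(state.T, before)
        assert result.times.size == 0

    def test_heating_is_monotone_after_start(self, model):
        """With a hot wall every voxel's temperature trend is upward."""
        vox = voxelize(mini_scene("single_peach_half"), 0.0015)
        state = FlowState.initial(vox, 20.0)
        snaps = []
        t_marks = iter([20.0, 40.0, 60.0])
        mark = next(t_marks)

        def grab(s):
            nonlocal mark
            if mark is not None and s.time >= mark:
                snaps.append(s.T.copy())
                mark = next(t_marks, None)

        run_phase(state, vox, model, ProcessPhase(100.0, 61.0), SolverConfig(),
                  step_callback=grab)
        for a, b in zip(snaps, snaps[1:]):
            assert np.all(b[vox.interior] >= a[vox.interior] - 0.1)
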