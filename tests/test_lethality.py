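"""F-value kinetics, field accumulation and critical-point location."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stillcan.fixtures import mini_scene
from stillcan.geometry import build_case, voxelize
from stillcan.lethality import (
    LethalityField,
    LethalityParams,
    integrate_f,
    interior_solid_mask,
    lethal_rate,
    locate_critical,
    per_particle_min_f,
    ramp_f_exact,
    slowest_heating_point,
    target_f,
)

P = LethalityParams()


class TestLethalRate:
    @pytest.mark.parametrize("T,expected", [(90.0, 1.0), (101.5, 10.0), (78.5, 0.1)])
    def test_reference_and_one_z_offsets(self, T, expected):
        assert lethal_rate(T, P) == pytest.approx(expected, rel=1e-12)


class TestIntegrateF:
    def test_constant_hold_at_reference(self):
        t = np.arange(0, 601.0, 1.0)
        assert integrate_f(t, np.full_like(t, 90.0), P) == pytest.approx(10.0)

    def test_constant_hold_at_100C(self):
        t = np.arange(0, 1201.0, 1.0)
        expected = 20.0 * 10 ** (10.0 / 11.5)  # ≈ 148.1 min
        f = integrate_f(t, np.full_like(t, 100.0), P)
        assert f == pytest.approx(expected, rel=1e-12)
        assert f == pytest.approx(148.11, abs=0.01)

    @pytest.mark.parametrize("T1,T2,minutes", [(20, 100, 10), (100, 60, 5), (85, 95, 30)])
    def test_linear_ramp_matches_closed_form(self, T1, T2, minutes):
        t = np.arange(0, minutes * 60 + 1.0, 1.0)
        temps = T1 + (T2 - T1) * t / (minutes * 60)
        exact = ramp_f_exact(T1, T2, minutes, P)
        assert integrate_f(t, temps, P) == pytest.approx(exact, rel=1e-4)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            integrate_f([0.0, 2.0, 1.0], [90.0, 90.0, 90.0], P)

    def test_bounded_by_hold_at_max_temperature(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 1201.0, 1.0)
        temps = 20 + 80 * rng.random(t.size)
        f = integrate_f(t, temps, P)
        assert f <= 20.0 * 10 ** (10.0 / 11.5) + 1e-12

    @given(shift=st.floats(min_value=0.0, max_value=15.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_monotone_in_temperature(self, shift):
        t = np.arange(0, 301.0, 1.0)
        base = 60 + 30 * np.sin(t / 40.0)
        assert integrate_f(t, base + shift, P) >= integrate_f(t, base, P)


class TestTargetF:
    def test_six_log_reduction_of_c_butyricum(self):
        assert target_f(P) == pytest.approx(6.6)

    def test_linearity(self):
        assert target_f(LethalityParams(log_reductions=0.0)) == 0.0
        assert target_f(LethalityParams(log_reductions=12.0)) == pytest.approx(13.2)

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError):
            LethalityParams(z=-1.0)


class TestFieldAccumulation:
    def test_uniform_minute_at_reference(self):
        field = LethalityField((3, 3, 3), P)
        T = np.full((3, 3, 3), 90.0)
        field.start(T, 0.0)
        field.accumulate(T, 60.0)
        assert np.allclose(field.F, 1.0)

    def test_subdivision_invariance_at_constant_T(self):
        T = np.full((2, 2, 2), 97.3)
        one = LethalityField((2, 2, 2), P)
        one.start(T, 0.0)
        one.accumulate(T, 120.0)
        two = LethalityField((2, 2, 2), P)
        two.start(T, 0.0)
        two.accumulate(T, 45.0)
        two.accumulate(T, 120.0)
        assert np.allclose(one.F, two.F, rtol=1e-12, atol=0)

    def test_matches_integrate_f_on_random_profile(self):
        rng = np.random.default_rng(42)
        times = np.cumsum(rng.uniform(0.2, 2.0, 200))
        temps = 20 + 80 * rng.random(times.size)
        field = LethalityField((1,), P)
        field.start(np.array([temps[0]]), float(times[0]))
        for t, T in zip(times[1:], temps[1:]):
            field.accumulate(np.array([T]), float(t))
        expected = integrate_f(times, temps, P)
        assert field.F[0] == pytest.approx(expected, rel=1e-12)

    def test_non_monotone_time_rejected(self):
        field = LethalityField((1,), P)
        field.start(np.array([90.0]), 10.0)
        with pytest.raises(ValueError):
            field.accumulate(np.array([90.0]), 10.0)


@pytest.fixture(scope="module")
def small_vox():
    return voxelize(build_case("upward"), 0.005)


class TestCriticalPoint:
    def test_uniform_field_tie_breaks_lexicographically(self, small_vox):
        field = LethalityField(small_vox.dims, P)
        field.F[:] = 5.0
        report = locate_critical(field, small_vox, "particles")
        solid_idx = np.argwhere(small_vox.solid)
        assert report.index == tuple(solid_idx[0])

    def test_planted_minimum_found(self, small_vox):
        field = LethalityField(small_vox.dims, P)
        field.F[:] = 50.0
        target = tuple(np.argwhere(small_vox.solid)[17])
        field.F[target] = 1.0
        report = locate_critical(field, small_vox, "particles")
        assert report.index == target
        assert report.F_min == 1.0
        assert report.particle_id == int(small_vox.particle_id[target])

    def test_empty_restriction_rejected(self):
        vox = voxelize(mini_scene("empty_can"), 0.0015)
        field = LethalityField(vox.dims, P)
        with pytest.raises(ValueError):
            locate_critical(field, vox, "particles")

    def test_everywhere_includes_fluid(self, small_vox):
        field = LethalityField(small_vox.dims, P)
        field.F[:] = 9.0
        fluid_idx = tuple(np.argwhere(small_vox.fluid)[0])
        field.F[fluid_idx] = 0.5
        report = locate_critical(field, small_vox, "everywhere")
        assert report.index == fluid_idx
        assert report.particle_id == -1

    def test_interior_mask_excludes_surface(self, small_vox):
        interior = interior_solid_mask(small_vox)
        assert interior.sum() > 0
        assert np.all(small_vox.solid[interior])
        assert interior.sum() < small_vox.solid.sum()

    def test_per_particle_minima_bracket_global(self, small_vox):
        field = LethalityField(small_vox.dims, P)
        rng = np.random.default_rng(3)
        field.F[:] = rng.uniform(10, 100, small_vox.dims)
        minima = per_particle_min_f(field, small_vox, interior_only=False)
        assert len(minima) == 4
        global_min = field.F[small_vox.solid].min()
        assert min(minima) == pytest.approx(global_min)


class TestSlowestHeatingPoint:
    def test_planted_cold_spot(self, small_vox):
        T = np.full(small_vox.dims, 95.0)
        spot = tuple(np.argwhere(small_vox.solid)[33])
        T[spot] = 40.0
        loc_mm, idx = slowest_heating_point(T, small_vox)
        assert idx == spot
        assert loc_mm == small_vox.index_to_mm(spot)

    def test_uniform_snapshot_tie_break(self, small_vox):
        T = np.full(small_vox.dims, 80.0)
        _, idx = slowest_heating_point(T, small_vox)
        assert idx == tuple(np.argwhere(small_vox.solid)[0])
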