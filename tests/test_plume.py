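import math

import numpy as np
import pytest

import mothsim as ms
from mothsim.plume import PlumeState, step_plume
from mothsim.wind import Velocity

from conftest import naive_plume_reference


class TestPuffOps:
    def test_single_euler_advection_step(self):
        p = ms.Puff(0.5, 0.5, 1e-6)
        q = ms.advect_puff(p, Velocity(1.0, 0.0), 0.01)
        assert (q.x, q.y) == (pytest.approx(0.51), 0.5)

    def test_zero_wind_leaves_center(self):
        p = ms.Puff(0.0, 0.5, 1e-6)
        q = ms.advect_puff(p, Velocity(0.0, 0.0), 1.0)
        assert (q.x, q.y) == (0.0, 0.5)

    def test_advection_telescopes_under_constant_wind(self):
        p = ms.Puff(0.0, 0.5, 1e-6)
        for _ in range(100):
            p = ms.advect_puff(p, Velocity(1.0, 0.1), 0.01)
        assert p.x == pytest.approx(1.0, abs=1e-9)
        assert p.y == pytest.approx(0.6, abs=1e-9)

    @pytest.mark.parametrize("r0, sigma, t, expected_r2", [
        # closed form r^2(t) = r0^2 + sigma * t
        (0.001, 0.0002, 1.0, 1e-6 + 2e-4),
        (0.001, 0.0004, 2.0, 8.01e-4),
        (0.001, 0.0, 5.0, 1e-6),
    ])
    def test_linear_squared_radius_growth(self, r0, sigma, t, expected_r2):
        params = ms.PlumeParams(r0=r0, spread_rate=sigma)
        p = ms.Puff(0.0, 0.5, r0 ** 2)
        steps = 100
        for _ in range(steps):
            p = ms.grow_puff(p, params, t / steps)
        assert p.r_squared == pytest.approx(expected_r2, rel=1e-9)
        if sigma == 0.0002:
            assert math.sqrt(p.r_squared) == pytest.approx(0.01418, abs=5e-5)


class TestRelease:
    def test_one_puff_per_step_at_matching_rate(self):
        state = PlumeState(ms.PlumeParams(release_rate=100.0))
        n = state.release(0.01)
        assert n == 1
        assert state.release_accumulator == pytest.approx(0.0, abs=1e-12)

    def test_release_count_telescopes_over_a_second(self):
        state = PlumeState(ms.PlumeParams(release_rate=50.0))
        total = sum(state.release(0.01) for _ in range(100))
        assert total == 50

    def test_fractional_accumulator_carries(self):
        state = PlumeState(ms.PlumeParams(release_rate=200.0))
        state.release_accumulator = 0.9
        n = state.release(0.001)
        assert n == 1
        assert state.release_accumulator == pytest.approx(0.1, abs=1e-9)


class TestConcentrationAndDetection:
    def test_empty_plume_has_zero_concentration(self):
        state = PlumeState(ms.PlumeParams())
        assert state.concentration_at(1.0, 0.5) == 0.0

    def test_peak_and_half_maximum(self):
        # one puff of width s = 1e-4 m^2 and unit mass
        params = ms.PlumeParams(r0=0.01, release_rate=100.0, spread_rate=0.0)
        state = PlumeState(params)
        state.release(0.01)  # puff born at the source with r^2 = 1e-4
        sx, sy = params.source_position
        assert state.concentration_at(sx, sy) == pytest.approx(5000.0)
        half_r = math.sqrt(2e-4 * math.log(2.0))
        assert state.concentration_at(sx + half_r, sy) == pytest.approx(2500.0)

    def test_detection_disc_boundary(self):
        params = ms.PlumeParams(r0=0.01, release_rate=100.0, spread_rate=0.0)
        state = PlumeState(params)
        state.release(0.01)
        sx, sy = params.source_position
        sensor = ms.SensorParams(threshold=2500.0)
        edge = math.sqrt(2e-4 * math.log(2.0))
        assert state.detect(sensor, sx + 0.999 * edge, sy)
        assert not state.detect(sensor, sx + 1.001 * edge, sy)
        # threshold above the peak: nothing detectable anywhere
        blind = ms.SensorParams(threshold=5001.0)
        assert not state.detect(blind, sx, sy)
        # at the center of an above-threshold puff: always detected
        assert state.detect(ms.SensorParams(threshold=4999.0), sx, sy)

    def test_raising_threshold_shrinks_detectable_region(self, rng):
        wind = ms.WindParams(meander_amplitude=0.1)
        params = ms.PlumeParams()
        state = PlumeState(params)
        for _ in range(300):
            step_plume(state, wind, params, 0.01)
        points = rng.uniform([0.0, 0.0], [2.0, 1.0], size=(300, 2))
        lo, hi = ms.SensorParams(600.0), ms.SensorParams(1200.0)
        for x, y in points:
            if state.detect(hi, x, y):
                assert state.detect(lo, x, y)


class TestStepPlume:
    def test_first_step_releases_floor_fr_dt(self):
        params = ms.PlumeParams(release_rate=100.0)
        state = PlumeState(params)
        step_plume(state, ms.WindParams(meander_amplitude=0.0), params, 0.01)
        assert state.n_active == 1
        assert state.released == 1

    def test_centerline_trail_without_meandering(self):
        params = ms.PlumeParams()
        state = PlumeState(params)
        wind = ms.WindParams(meander_amplitude=0.0)
        for _ in range(150):
            step_plume(state, wind, params, 0.01)
        _, y, _ = state.positions()
        np.testing.assert_allclose(y, 0.5, atol=1e-12)

    def test_oldest_puff_advects_across_the_arena(self):
        params = ms.PlumeParams()
        state = PlumeState(params)
        wind = ms.WindParams(meander_amplitude=0.0)
        for _ in range(250):  # 2.5 s at 1 m/s
            step_plume(state, wind, params, 0.01)
        x, _, _ = state.positions()
        # oldest survivor sits near x = 2 m or has already been pruned
        assert x.max() <= 2.0 + math.sqrt(state.positions()[2].max()) + 1e-9
        assert state.pruned > 0 or x.max() == pytest.approx(2.0, abs=0.02)

    def test_conservation_and_radius_monotonicity(self):
        params = ms.PlumeParams()
        state = PlumeState(params)
        wind = ms.WindParams(meander_amplitude=0.15)
        prev_r2_by_birth: dict[float, float] = {}
        for _ in range(400):
            step_plume(state, wind, params, 0.01)
            assert state.released - state.pruned == state.n_active
            _, _, r2 = state.positions()
            for tb, r2i in zip(state._tb, r2):
                assert r2i >= prev_r2_by_birth.get(tb, 0.0) - 1e-15
                prev_r2_by_birth[tb] = r2i

    def test_binary_field_symmetric_about_centerline(self):
        params = ms.PlumeParams()
        state = PlumeState(params)
        wind = ms.WindParams(meander_amplitude=0.0)
        for _ in range(200):
            step_plume(state, wind, params, 0.01)
        sensor = ms.SensorParams()
        for x in np.linspace(0.05, 1.9, 23):
            for d in (0.005, 0.01, 0.02):
                assert (state.detect(sensor, x, 0.5 + d)
                        == state.detect(sensor, x, 0.5 - d))


class TestVectorizedAgainstNaiveReference:
    def test_state_matches_per_puff_reference(self):
        """The O(1)-advection plume equals the explicit per-puff update."""
        params = ms.PlumeParams(release_rate=80.0)
        wind = ms.WindParams(meander_amplitude=0.12, meander_omega=0.8)
        dt = 0.01
        winds = [ms.wind_velocity(wind, i * dt) for i in range(120)]
        state = PlumeState(params)
        ref_gen = naive_plume_reference(params, winds, dt)
        for w in winds:
            state.step(w, dt)
            ref_puffs = next(ref_gen)
            x, y, r2 = state.positions()
            assert len(ref_puffs) == state.n_active
            np.testing.assert_allclose(x, [p.x for p in ref_puffs], atol=1e-10)
            np.testing.assert_allclose(y, [p.y for p in ref_puffs], atol=1e-10)
            np.testing.assert_allclose(r2, [p.r_squared for p in ref_puffs],
                                       atol=1e-12)


@pytest.mark.parametrize("bad", [
    dict(release_rate=0.0), dict(r0=0.0), dict(spread_rate=-1e-9),
    dict(puff_mass=0.0),
])
def test_invalid_plume_params_rejected(bad):
    with pytest.raises(ValueError):
        ms.PlumeParams(**bad)
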