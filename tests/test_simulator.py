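"""Langevin/metadynamics engine: CV projection, hills, integrator physics,
first-passage trajectories."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

import stimetad as st
from stimetad.errors import InvalidSequenceError
from stimetad.potential import SADDLE, START, Position2D, potential_energy
from stimetad.simulator import (
    HillList,
    MetaDConfig,
    SimulationConfig,
    bias_value,
    cv_project,
    deposit_hill,
    deposition_rate_to_period,
    langevin_step,
    run_fpt_trajectory,
)

KBT = 0.00831446261815324 * 300.0  # kJ/mol at 300 K


class TestCvProject:
    def test_zero_angle_is_projection_on_good_cv(self):
        assert cv_project((1.0, 2.0), 0.0, np.array([1.0, 0.0])) == pytest.approx(1.0)

    def test_ninety_degrees_swaps_to_orthogonal_axis(self):
        assert cv_project((1.0, 2.0), 90.0, np.array([1.0, 0.0])) == pytest.approx(
            2.0, abs=1e-12
        )

    def test_56_degrees_hand_trigonometry(self):
        expected = math.cos(math.radians(56)) + math.sin(math.radians(56))
        assert cv_project((1.0, 1.0), 56.0, np.array([1.0, 0.0])) == pytest.approx(
            expected
        )

    def test_default_direction_separates_the_wells(self):
        s_start = cv_project(START)
        s_target = cv_project(st.SECOND_MIN)
        assert s_start * s_target < 0  # opposite sides of the saddle
        assert abs(cv_project(SADDLE)) < 0.2


class TestHills:
    def cfg(self, **kw):
        return MetaDConfig(**kw)

    def test_empty_hill_list_has_zero_bias_everywhere(self):
        hills = HillList.from_metad(self.cfg())
        for s in [-3.0, 0.0, 0.17, 2.5]:
            assert bias_value(hills, s) == 0.0

    def test_single_hill_peaks_at_its_height(self):
        cfg = self.cfg()
        hills = deposit_hill(HillList.from_metad(cfg), s=0.5, t=1.0, cfg=cfg)
        assert bias_value(hills, 0.5) == pytest.approx(cfg.hill_height_h0)

    def test_first_hill_height_is_exactly_h0(self):
        cfg = self.cfg()
        hills = deposit_hill(HillList.from_metad(cfg), s=-1.23, t=1.0, cfg=cfg)
        assert hills.heights[0] == cfg.hill_height_h0

    def test_second_hill_at_same_center_is_tempered(self):
        """Well-tempered rule: h2 = h0 * exp(-h0/(gamma-1)); for h0 = 0.5 kBT,
        gamma = 5 this is 0.5 * exp(-0.125)."""
        cfg = self.cfg(hill_height_h0=0.5, bias_factor_gamma=5.0)
        hills = deposit_hill(HillList.from_metad(cfg), s=0.0, t=1.0, cfg=cfg)
        hills = deposit_hill(hills, s=0.0, t=2.0, cfg=cfg)
        assert hills.heights[1] == pytest.approx(0.5 * math.exp(-0.125), rel=1e-12)

    def test_two_identical_hills_sum_at_center(self):
        cfg = self.cfg()
        hills = deposit_hill(HillList.from_metad(cfg), s=0.2, t=1.0, cfg=cfg)
        hills = deposit_hill(hills, s=0.2, t=2.0, cfg=cfg)
        assert bias_value(hills, 0.2) == pytest.approx(float(hills.heights.sum()))

    def test_hundred_depositions_have_nonincreasing_heights(self):
        cfg = self.cfg()
        hills = HillList.from_metad(cfg)
        for i in range(100):
            hills = deposit_hill(hills, s=0.0, t=float(i + 1), cfg=cfg)
        assert np.all(np.diff(hills.heights) <= 1e-15)
        assert np.all(hills.heights <= cfg.hill_height_h0)

    def test_nonmonotone_deposit_time_rejected(self):
        cfg = self.cfg()
        hills = deposit_hill(HillList.from_metad(cfg), s=0.0, t=5.0, cfg=cfg)
        with pytest.raises(InvalidSequenceError):
            deposit_hill(hills, s=0.1, t=5.0, cfg=cfg)

    @given(centers=hst.lists(hst.floats(-2.0, 2.0), min_size=1, max_size=30))
    def test_bias_nonnegative_and_nondecreasing_in_time(self, centers):
        """Adding hills can only raise the bias at any fixed point."""
        cfg = self.cfg()
        hills = HillList.from_metad(cfg)
        probe = 0.37
        prev = 0.0
        for i, c in enumerate(centers):
            hills = deposit_hill(hills, s=c, t=float(i + 1), cfg=cfg)
            cur = bias_value(hills, probe)
            assert cur >= prev - 1e-12
            prev = cur


class TestDepositionRate:
    def test_rate_to_period_round_numbers(self):
        assert deposition_rate_to_period(10.0, 1.0) == 100_000
        assert deposition_rate_to_period(1000.0, 1.0) == 1000

    def test_non_integer_period_rejected(self):
        with pytest.raises(ValueError):
            deposition_rate_to_period(3.0, 1.0)


class TestLangevinStep:
    def test_stationary_point_stays_put_without_noise(self):
        """friction = 0 turns off the thermostat noise; zero velocity at a
        stationary point is a fixed point of the integrator."""
        cfg = SimulationConfig(friction=0.0)
        p = np.array([START.x, START.y])
        v = np.zeros(2)
        rng = np.random.default_rng(0)
        f = None
        for _ in range(100):
            p, v, f = langevin_step(p, v, cfg, rng, force=f)
        assert np.allclose(p, [START.x, START.y], atol=1e-9)

    def test_energy_conservation_in_frictionless_limit(self):
        """With friction = 0 the scheme is velocity Verlet; total energy over
        10^4 steps drifts by < 1e-4 relative."""
        cfg = SimulationConfig(friction=0.0)
        p = np.array([START.x + 0.3, START.y - 0.2])
        v = np.zeros(2)
        rng = np.random.default_rng(1)

        def energy(p_, v_):
            return KBT * potential_energy(Position2D(*p_)) + 0.5 * cfg.mass * (
                v_ @ v_
            )

        e0 = energy(p, v)
        f = None
        for _ in range(10_000):
            p, v, f = langevin_step(p, v, cfg, rng, force=f)
        assert abs(energy(p, v) - e0) / abs(e0) < 1e-4

    def test_overdamped_drift_fpt_matches_closed_form(self):
        """Constant tilt f over distance L: mean FPT = L m gamma / f, the
        drift-dominated closed form, within 20% over 200 seeds."""
        cfg = SimulationConfig(mass=40.0, friction=0.01, timestep=1.0)
        f_const = np.array([100.0, 0.0])  # kJ/mol/nm, Peclet = fL/kT ~ 40
        length = 1.0  # nm
        expected_ps = length * cfg.mass * (cfg.friction * 1e3) / f_const[0]
        fpts = []
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = np.zeros(2)
            v = np.zeros(2)
            f = f_const
            steps = 0
            while p[0] < length and steps < 100_000:
                p, v, f = langevin_step(
                    p, v, cfg, rng, force=f, force_fn=lambda _: f_const
                )
                steps += 1
            fpts.append(steps * cfg.timestep * 1e-3)  # ps
        assert np.mean(fpts) == pytest.approx(expected_ps, rel=0.20)


class TestRunFptTrajectory:
    SIM = SimulationConfig(potential_scale=0.8, max_steps=20_000_000)

    def test_start_inside_target_returns_zero_fpt(self):
        sim = SimulationConfig(start=Position2D(-1.5, 1.2))
        traj = run_fpt_trajectory(sim, None, rng=0)
        assert traj.reached and traj.fpt_physical == 0.0
        assert traj.bias_series.size == 0

    def test_same_seed_reproduces_bit_identical_trajectory(self):
        metad = MetaDConfig(hill_height_h0=0.4, deposition_period=5000)
        a = run_fpt_trajectory(self.SIM, metad, rng=42)
        b = run_fpt_trajectory(self.SIM, metad, rng=42)
        assert a.fpt_physical == b.fpt_physical
        assert np.array_equal(a.bias_series, b.bias_series)
        assert np.array_equal(a.hills.centers, b.hills.centers)

    def test_bias_series_length_matches_physical_fpt(self):
        metad = MetaDConfig(hill_height_h0=0.4, deposition_period=5000)
        traj = run_fpt_trajectory(self.SIM, metad, rng=3)
        assert traj.reached
        assert traj.bias_series.size * traj.timestep * 1e-6 == pytest.approx(
            traj.fpt_physical
        )
        assert traj.bias_series.min() >= 0.0

    def test_deposited_heights_respect_well_tempered_bound(self):
        metad = MetaDConfig(hill_height_h0=0.4, deposition_period=2000)
        traj = run_fpt_trajectory(self.SIM, metad, rng=5)
        assert len(traj.hills) >= 2
        assert np.all(traj.hills.heights <= metad.hill_height_h0 + 1e-15)
        assert np.all(np.diff(traj.hills.deposit_times) > 0)

    def test_censored_run_flags_not_reached(self):
        sim = SimulationConfig(potential_scale=1.0, max_steps=2000)
        traj = run_fpt_trajectory(sim, None, rng=1)
        assert not traj.reached
        assert traj.bias_series.size == 2000
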