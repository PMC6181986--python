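"""Tests of the input generators and behaviour schedules."""

import numpy as np
import pytest

from preplaynet.core_dynamics import THETA_F
from preplaynet.stimuli import (
    BurstGate,
    ECInput,
    ExtInput,
    OUParams,
    OUProcess,
    SingleCellInputs,
    TriggerProcess,
    moving_1d,
    ou_step,
    position_1d,
    theta_drive,
    ymaze_position,
)


class TestOUProcess:
    def test_deterministic_decay(self, rng):
        s = np.array([1.0])
        p = OUParams(tau=10.0, sigma=0.0)
        for _ in range(10):
            s = ou_step(s, p, 1.0, rng)
        assert s[0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_stationary_variance(self, rng):
        # sigma^2 * tau / 2 = 0.05 for tau=10, sigma=0.1
        proc = OUProcess(4000, tau=10.0, sigma=0.1)
        for _ in range(200):  # burn-in to stationarity
            proc.step(1.0, rng)
        samples = []
        for _ in range(300):
            samples.append(proc.step(1.0, rng).copy())
        var = np.var(np.concatenate(samples))
        assert var == pytest.approx(0.05, rel=0.1)

    def test_lag_tau_autocorrelation(self, rng):
        proc = OUProcess(8000, tau=10.0, sigma=0.1)
        for _ in range(200):
            proc.step(1.0, rng)
        s0 = proc.s.copy()
        for _ in range(10):  # advance by exactly tau
            proc.step(1.0, rng)
        r = np.corrcoef(s0, proc.s)[0, 1]
        assert r == pytest.approx(np.exp(-1.0), rel=0.1)


class TestSingleCellInputs:
    def _mean_currents(self, condition, seconds=60, seed=5, literal=False):
        rng = np.random.default_rng(seed)
        gen = SingleCellInputs(condition, 1, literal_mapping=literal)
        a, ap = [], []
        for k in range(seconds * 1000):
            gen.step(k * 1.0, 1.0, rng)
            if k % 10 == 0:
                a.append(gen.f_som.I[0, :10].mean())
                ap.append(gen.f_dnd.I[0, :10].mean())
        return np.array(a), np.array(ap)

    def test_correlated_condition_shares_source(self):
        a, ap = self._mean_currents("correlated")
        assert np.corrcoef(a, ap)[0, 1] > 0.5

    def test_uncorrelated_condition_is_independent(self):
        a, ap = self._mean_currents("uncorrelated")
        assert abs(np.corrcoef(a, ap)[0, 1]) < 0.1

    def test_literal_mapping_swaps_conditions(self):
        a, ap = self._mean_currents("uncorrelated", literal=True)
        assert np.corrcoef(a, ap)[0, 1] > 0.5

    def test_majority_groups_uncorrelated(self):
        rng = np.random.default_rng(5)
        gen = SingleCellInputs("correlated", 1)
        b, bp = [], []
        for k in range(60000):
            gen.step(k * 1.0, 1.0, rng)
            if k % 10 == 0:
                b.append(gen.f_som.I[0, 10:].mean())
                bp.append(gen.f_dnd.I[0, 10:].mean())
        assert abs(np.corrcoef(b, bp)[0, 1]) < 0.1

    def test_rates_bounded_by_phi_input(self, rng):
        gen = SingleCellInputs("correlated", 3)
        for k in range(500):
            u_som, u_dnd = gen.step(k * 1.0, 1.0, rng)
        assert np.all(u_som >= 0) and np.all(u_som <= 0.08)
        assert np.all(u_dnd >= 0) and np.all(u_dnd <= 0.08)

    def test_stability_condition_switches_sources(self, rng):
        gen = SingleCellInputs("stability", 1, phase_times=(100.0, 200.0))
        s = np.arange(1.0, 22.0)[None, :]
        gen.sources.s = s.copy()
        d0 = gen._dendritic_drive(s, 50.0)
        d1 = gen._dendritic_drive(s, 150.0)
        d2 = gen._dendritic_drive(s, 250.0)
        # phase 1: all independent sources 2..21
        np.testing.assert_array_equal(d0[0], np.arange(2.0, 22.0))
        # phase 2: first group tied to the somatic source
        assert np.all(d1[0, :10] == 1.0) and np.all(d1[0, 10:] == np.arange(12.0, 22.0))
        # phase 3: second group tied instead
        assert np.all(d2[0, 10:] == 1.0) and np.all(d2[0, :10] == np.arange(2.0, 12.0))

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            SingleCellInputs("mystery", 1)


class TestTrackSchedule:
    def test_printed_waypoints(self):
        assert position_1d(16.0) == pytest.approx(1.0)
        assert position_1d(44.0) == pytest.approx(0.8)
        assert position_1d(3.0) == pytest.approx(0.0)
        assert position_1d(30.0) == pytest.approx(0.5)

    def test_continuity_at_segment_boundaries(self):
        breaks = [10, 15, 17.5, 22.5, 25, 35, 37.5, 40, 44, 47]
        eps = 1e-9
        for b in breaks:
            left = position_1d(b - eps)
            right = position_1d(b + eps)
            assert left == pytest.approx(right, abs=1e-6), f"discontinuity at {b}"

    def test_moving_flags(self):
        assert moving_1d(12.0) and moving_1d(42.0)
        assert not moving_1d(16.0)      # paused at the far end
        assert not moving_1d(3.0)       # initial immobility
        assert not moving_1d(23.5)


class TestYmazeSchedule:
    def test_cycle_structure(self):
        arm, pos, mov = ymaze_position(5.0)
        assert (arm, pos, mov) == (1, 0.0, False)
        arm, pos, mov = ymaze_position(14.0)   # cycle 1, outbound on arm 1
        assert arm == 1 and 0 < pos < 0.5 and mov
        arm, pos, mov = ymaze_position(24.0)   # cycle 2 visits arm 2
        assert arm == 2
        arm, pos, mov = ymaze_position(34.0)
        assert arm == 3
        arm, pos, mov = ymaze_position(44.0)   # wraps back to arm 1
        assert arm == 1

    def test_arm_end_plateau(self):
        for t in (16.0, 26.5, 37.0):
            _, pos, mov = ymaze_position(t + 0.0)
        arm, pos, mov = ymaze_position(10.0 + 6.0)  # within [5, 7.5) of cycle
        assert pos == pytest.approx(0.5) and not mov

    def test_continuity_within_cycle(self):
        ts = np.linspace(10.0, 20.0, 4001)
        pos = np.array([ymaze_position(t)[1] for t in ts])
        assert np.max(np.abs(np.diff(pos))) < 0.001


class TestECInput:
    def test_place_tuning_peak_value(self, rng):
        ec = ECInput("place", 10, 0, rng, sigma_n=0.0)
        cur = ec.tuned_current(ec.centers[3])
        assert cur[3] == pytest.approx(5.0)
        # assembled current at field centre, theta at zero crossing
        u = ec.step(ec.centers[3], 1, True, 0.0, False, 1.0, rng)
        from scipy.special import expit

        assert u[3] == pytest.approx(0.08 * expit(5.0 - 0.5 - THETA_F), rel=1e-12)

    def test_grid_tuning_range_and_period(self, rng):
        ec = ECInput("grid", 200, 0, rng)
        pos = np.linspace(0, 1, 2001)
        vals = np.array([ec.tuned_current(p) for p in pos])
        assert vals.max() <= 5.0 * np.exp(3.0) + 1e-9
        assert vals.min() >= 5.0 * np.exp(-3.0) - 1e-9
        # periodicity of one unit in its own period
        i = 7
        p0 = 0.1
        v0 = ec.tuned_current(p0)[i]
        v1 = ec.tuned_current(p0 + ec.grid_period[i])[i]
        assert v0 == pytest.approx(v1, rel=1e-9)

    def test_grid_parameter_distributions(self):
        ec = ECInput("grid", 10000, 0, np.random.default_rng(0))
        assert 0.2 <= ec.grid_period.min() and ec.grid_period.max() <= 0.6
        assert ec.grid_period.mean() == pytest.approx(0.4, abs=0.01)
        assert ec.grid_phase.mean() == pytest.approx(np.pi, abs=0.1)
        assert ec.grid_phase.min() >= 0 and ec.grid_phase.max() <= 2 * np.pi

    def test_ymaze_off_arm_silent(self, rng):
        ec = ECInput("ymaze", 30, 0, rng)
        cur = ec.tuned_current(0.25, arm=2)
        assert np.all(cur[ec.center_arm != 2] == 0.0)

    def test_immobility_is_noise_only(self, rng):
        ec = ECInput("place", 10, 0, rng, sigma_n=0.0)
        from scipy.special import expit

        u = ec.step(0.5, 1, False, 10.0, False, 1.0, rng)
        np.testing.assert_allclose(u, 0.08 * expit(-THETA_F))

    def test_center_resampling_keeps_track_prefix(self):
        rng = np.random.default_rng(1)
        ec = ECInput("random", 500, 0, rng)
        before = ec.centers.copy()
        ec.resample_centers(rng, keep_below=0.2)
        kept = before <= 0.2
        np.testing.assert_array_equal(ec.centers[kept], before[kept])
        assert np.any(ec.centers[~kept] != before[~kept])


class TestTriggersAndBursts:
    def test_pulse_duration(self, rng):
        trig = TriggerProcess(rate_hz=0.0, pulse_ms=10.0, amp=10.0)
        trig.force(10.0)
        vals = [trig.step(1.0, False, rng) for _ in range(20)]
        assert sum(v > 0 for v in vals) == 10

    def test_poisson_rate(self):
        rng = np.random.default_rng(2)
        trig = TriggerProcess(rate_hz=1.0, pulse_ms=10.0, amp=10.0)
        onsets = 0
        prev = 0.0
        for _ in range(600_000):  # 600 s
            v = trig.step(1.0, True, rng)
            if v > 0 and prev == 0.0:
                onsets += 1
            prev = v
        assert abs(onsets - 600) < 3 * np.sqrt(600)

    def test_burst_duration_exact(self):
        rng = np.random.default_rng(3)
        gate = BurstGate(rate_hz=1.0, burst_ms=200.0)
        trace = [gate.step(1.0, rng) for _ in range(200_000)]
        trace = np.array(trace + [0.0])
        edges = np.flatnonzero(np.diff(trace) != 0)
        lengths = np.diff(edges)[::2] if trace[edges[0] + 1] else np.diff(edges)[1::2]
        assert np.all(lengths >= 200)  # merged bursts can only be longer

    def test_burst_count_poisson(self):
        rng = np.random.default_rng(4)
        gate = BurstGate(rate_hz=1.0, burst_ms=200.0)
        onsets = 0
        prev = 0.0
        for _ in range(600_000):
            v = gate.step(1.0, rng)
            if v and not prev:
                onsets += 1
            prev = v
        # onsets only start outside bursts; rate is thinned by the 20% duty cycle
        expected = 600 / 1.2
        assert abs(onsets - expected) < 4 * np.sqrt(expected)


class TestExtInput:
    def test_silent_baseline(self, rng):
        ext = ExtInput(20, targets=[0, 1], sigma_n=0.0)
        np.testing.assert_array_equal(ext.step(0.0, 0.0, 1.0, rng), np.zeros(20))

    def test_bipolar_trigger_sign_structure(self, rng):
        ext = ExtInput(20, targets=np.arange(10), bipolar=True, sigma_n=0.0)
        v = ext.step(0.0, 10.0, 1.0, rng)
        assert np.all(v[:10] == 10.0) and np.all(v[10:] == -10.0)

    def test_positive_only_trigger(self, rng):
        ext = ExtInput(20, targets=np.arange(5), bipolar=False, sigma_n=0.0)
        v = ext.step(0.0, 5.0, 1.0, rng)
        assert np.all(v[:5] == 5.0) and np.all(v[5:] == 0.0)

    def test_theta_is_global(self, rng):
        ext = ExtInput(8, targets=[0], sigma_n=0.0)
        th = theta_drive(250.0)
        np.testing.assert_allclose(ext.step(th, 0.0, 1.0, rng), th)
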