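"""Clock counters, beacon-based timestamp adjustment, drift fitting, link stats."""

import numpy as np
import pytest

from insolegait.sync import (
    ClockSpec, SyncSample, adjust_timestamp, analyze_drift, max_recording_time,
    max_timer_error, packet_error_rate, rssi_per_correlation, simulate_sensor_clock,
)


class TestCounterLimits:
    def test_default_counter_wraps_after_twelve_hours(self):
        assert max_recording_time(ClockSpec()) == pytest.approx(11.93, abs=0.005)

    def test_sixteen_bit_second_counter(self):
        spec = ClockSpec(tick_s=1.0, counter_bits=16)
        assert max_recording_time(spec) == pytest.approx(65536 / 3600)

    def test_zero_tick_zero_time(self):
        assert max_recording_time(ClockSpec(tick_s=0.0)) == 0.0

    def test_worst_case_oscillator_error(self):
        assert max_timer_error(ClockSpec()) == pytest.approx(0.43, abs=0.005)

    def test_timer_error_linear_in_tolerance_and_tick(self):
        base = max_timer_error(ClockSpec())
        assert max_timer_error(ClockSpec(f_tol_ppm=20.0)) == pytest.approx(2 * base)
        assert max_timer_error(ClockSpec(f_tol_ppm=0.0)) == 0.0
        assert max_timer_error(ClockSpec(tick_s=20e-6)) == pytest.approx(2 * base)

    def test_counter_bits_validated(self):
        with pytest.raises(ValueError):
            ClockSpec(counter_bits=8)


class TestAdjustTimestamp:
    def test_identity_when_clocks_agree(self):
        s = SyncSample(t_mn_sync=500, t_sn_sync=500, t_rf_sn_sync=0, t_rf_sn_proc=0)
        assert adjust_timestamp(s, 1234) == 1234

    def test_offset_arithmetic(self):
        s = SyncSample(t_mn_sync=100, t_sn_sync=40, t_rf_sn_sync=0, t_rf_sn_proc=10)
        assert adjust_timestamp(s, 50) == 100

    def test_wraps_modulo_counter(self):
        spec = ClockSpec(counter_bits=16, tick_s=1.0)
        s = SyncSample(t_mn_sync=65530, t_sn_sync=0, t_rf_sn_sync=0, t_rf_sn_proc=0)
        assert adjust_timestamp(s, 10, spec) == 4

    def test_negative_processing_delay_rejected(self):
        s = SyncSample(t_mn_sync=0, t_sn_sync=0, t_rf_sn_sync=10, t_rf_sn_proc=5)
        with pytest.raises(ValueError):
            adjust_timestamp(s, 0)

    def test_simulated_log_adjusts_to_true_master_time(self):
        log = simulate_sensor_clock(ClockSpec(), 10.0, jitter_ticks=2.0,
                                    duration_s=600.0, seed=4)
        adj = log.t_mn_sync + log.t_sn - log.t_sn_sync - log.dt_proc
        err_ticks = adj - log.t_true_mn
        # constant processing-latency offset plus jitter-level spread only
        assert np.ptp(err_ticks) <= 15
        assert abs(np.median(err_ticks)) <= 70


class TestSimulation:
    def test_zero_drift_constant_deviation(self):
        log = simulate_sensor_clock(ClockSpec(), 0.0, jitter_ticks=0.0,
                                    duration_s=300.0, seed=1)
        dev = log.t_mn_sync - log.t_sn_sync
        assert np.ptp(dev) <= 1  # only integer rounding of the constant offset

    def test_ten_ppm_accumulates_36ms_per_hour(self):
        log = simulate_sensor_clock(ClockSpec(), 10.0, jitter_ticks=0.0,
                                    duration_s=3600.0, seed=2)
        dev_s = (log.t_mn_sync - log.t_sn_sync).astype(float) * log.spec.tick_s
        assert dev_s[-1] - dev_s[0] == pytest.approx(-10e-6 * 3599, rel=0.01)

    def test_miss_probability_flags_about_half(self):
        log = simulate_sensor_clock(ClockSpec(), 5.0, miss_prob=0.5,
                                    duration_s=2000.0, seed=3)
        assert 0.4 <= log.missed.mean() <= 0.6

    def test_duration_beyond_counter_rejected(self):
        with pytest.raises(ValueError):
            simulate_sensor_clock(ClockSpec(), 0.0, duration_s=13 * 3600.0)

    def test_reproducible_for_fixed_seed(self):
        a = simulate_sensor_clock(ClockSpec(), 7.0, duration_s=60.0, seed=9)
        b = simulate_sensor_clock(ClockSpec(), 7.0, duration_s=60.0, seed=9)
        np.testing.assert_array_equal(a.t_sn_sync, b.t_sn_sync)
        np.testing.assert_array_equal(a.missed, b.missed)


class TestDriftAnalysis:
    def test_recovers_injected_divergence(self):
        # slave running 11.69 ppm fast -> master-minus-slave slope of -11.69 us/s
        log = simulate_sensor_clock(ClockSpec(), 11.69, jitter_ticks=2.0,
                                    duration_s=3600.0, seed=5)
        rep = analyze_drift(log)
        assert rep.p1_us_per_s == pytest.approx(-11.69, abs=0.5)
        assert rep.passed

    def test_adjusted_divergence_below_one_us_per_s(self):
        log = simulate_sensor_clock(ClockSpec(), 10.0, jitter_ticks=2.0,
                                    duration_s=3600.0, seed=6)
        rep = analyze_drift(log)
        assert rep.abs_adjusted_divergence_us_per_s < 1.0

    def test_gross_drift_fails_timing_test(self):
        log = simulate_sensor_clock(ClockSpec(), 50000.0, duration_s=1800.0, seed=7)
        assert not analyze_drift(log).passed

    def test_zero_drift_indicators_near_zero(self):
        log = simulate_sensor_clock(ClockSpec(), 0.0, jitter_ticks=1.0,
                                    duration_s=1200.0, seed=8)
        rep = analyze_drift(log)
        assert abs(rep.p1_us_per_s) < 0.5
        assert rep.passed

    def test_too_short_log_rejected(self):
        log = simulate_sensor_clock(ClockSpec(), 0.0, duration_s=5.0, seed=1)
        with pytest.raises(ValueError):
            analyze_drift(log)


class TestLinkStats:
    @pytest.mark.parametrize("rx,exp,per", [(95, 100, 5.0), (100, 100, 0.0)])
    def test_packet_error_rate(self, rx, exp, per):
        assert packet_error_rate(rx, exp) == pytest.approx(per)

    def test_per_requires_expected(self):
        with pytest.raises(ValueError):
            packet_error_rate(5, 0)

    def test_per_brute_force(self, rng):
        rx = rng.integers(0, 100, size=20)
        for r in rx:
            assert packet_error_rate(int(r), 100) == pytest.approx(100 * (1 - r / 100))

    def test_linear_relation_gives_unit_correlation(self):
        rssi = np.array([-40.0, -55.0, -62.0, -78.0, -81.0])
        per = 0.3 * np.abs(rssi) - 2.0
        assert rssi_per_correlation(rssi, per) == pytest.approx(1.0)

    def test_independent_noise_low_correlation(self, rng):
        rssi = rng.normal(-60, 8, size=500)
        per = rng.uniform(0, 10, size=500)
        assert abs(rssi_per_correlation(rssi, per)) < 0.15

    def test_constant_per_missing_value(self):
        assert np.isnan(rssi_per_correlation([-50.0, -60.0, -70.0], [5.0, 5.0, 5.0]))
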