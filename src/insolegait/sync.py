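"""Body-sensor-network clock synchronization and drift diagnostics.

A master node broadcasts a re-synchronization beacon every second carrying its
global timestamp (32-bit counter, 10 µs resolution).  Each sensor node records
the beacon's master timestamp, its own local timestamp, and the local
processing delay between radio reception and timestamping; any later local
sample time can then be mapped onto the global clock:

    MN_T_SN[k] = T_MN_sync + T_SN[k] - T_SN_sync - dT_proc

When a beacon is missed the previous correction is retained until the next
one arrives.  This module provides the analytic counter limits (maximum
recording time, worst-case oscillator error), a drifting-slave-clock
simulator, the quadratic drift fit used to grade oscillators (divergence,
linearity, RMSE about the linear part, pass/fail at 1 ms/s), and the simple
link-quality statistics (packet error rate, |RSSI|-PER correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

__all__ = [
    "ClockSpec",
    "SyncSample",
    "SyncLog",
    "DriftReport",
    "max_recording_time",
    "max_timer_error",
    "adjust_timestamp",
    "simulate_sensor_clock",
    "analyze_drift",
    "packet_error_rate",
    "rssi_per_correlation",
]

FAIL_THRESHOLD_US_PER_S = 1000.0  # divergence above 1 ms/s fails the timing test


@dataclass
class ClockSpec:
    """Counter geometry and oscillator tolerance of the network clock."""

    tick_s: float = 10e-6          # counter resolution
    counter_bits: int = 32
    f_tol_ppm: float = 10.0        # oscillator frequency tolerance (one-sided)
    sync_period_s: float = 1.0     # beacon interval

    def __post_init__(self) -> None:
        if self.tick_s < 0:
            raise ValueError("tick must be non-negative")
        if not (16 <= self.counter_bits <= 64):
            raise ValueError("counter_bits must lie in [16, 64]")
        if self.sync_period_s <= 0:
            raise ValueError("sync_period must be positive")

    @property
    def modulus(self) -> int:
        return 1 << self.counter_bits


def max_recording_time(spec: ClockSpec) -> float:
    """Hours until the counter wraps: 2^bits * tick / 3600."""
    return spec.modulus * spec.tick_s / 3600.0


def max_timer_error(spec: ClockSpec) -> float:
    """Worst-case accumulated oscillator error [s] over a full counter span."""
    return spec.modulus * spec.tick_s * spec.f_tol_ppm * 1e-6


@dataclass
class SyncSample:
    """Correction state from one (possibly retained) synchronization beacon."""

    t_mn_sync: int       # master timestamp in ticks
    t_sn_sync: int       # local sensor timestamp in ticks
    t_rf_sn_sync: int    # RF-clock reception timestamp in ticks
    t_rf_sn_proc: int    # RF-clock processing timestamp in ticks

    @property
    def dt_proc(self) -> int:
        d = self.t_rf_sn_proc - self.t_rf_sn_sync
        if d < 0:
            raise ValueError("processing delay must be non-negative")
        return d


def adjust_timestamp(sample: SyncSample, t_sn: int, spec: ClockSpec | None = None) -> int:
    """Map a local sensor timestamp onto the global master clock (ticks).

    ``sample`` must hold the most recently received beacon (stale values are
    retained on a miss).  Counter wrap is handled modulo 2^bits.
    """
    out = sample.t_mn_sync + t_sn - sample.t_sn_sync - sample.dt_proc
    if spec is not None:
        out %= spec.modulus
    return out


@dataclass
class SyncLog:
    """Per-beacon synchronization records of one simulated (or parsed) device.

    Arrays are aligned on beacon index ``k`` (one per ``sync_period``).  The
    ``*_sync`` columns hold the correction state in effect at beacon ``k``
    (stale when ``missed[k]``); ``t_sn`` is the local sensor timestamp at the
    true beacon instant and ``t_true_mn`` the exact master timestamp, kept as
    simulation ground truth.
    """

    spec: ClockSpec
    t_mn_sync: np.ndarray
    t_sn_sync: np.ndarray
    dt_proc: np.ndarray
    t_sn: np.ndarray
    t_true_mn: np.ndarray
    missed: np.ndarray
    fs_hz: float = 1.0

    def sample(self, k: int) -> SyncSample:
        return SyncSample(
            int(self.t_mn_sync[k]), int(self.t_sn_sync[k]),
            0, int(self.dt_proc[k]),
        )

    @property
    def n(self) -> int:
        return len(self.t_mn_sync)


def simulate_sensor_clock(
    spec: ClockSpec,
    drift_ppm: float,
    jitter_ticks: float = 2.0,
    miss_prob: float = 0.0,
    duration_s: float = 3600.0,
    seed: int | None = None,
    quad_ppm_per_hour: float = 0.0,
) -> SyncLog:
    """Simulate a slave clock drifting against the master over one recording.

    The slave oscillator runs at ``1 + drift_ppm*1e-6`` times the master rate
    (optionally with a slow quadratic component); beacons arrive every
    ``sync_period`` with Gaussian reception jitter of ``jitter_ticks`` ticks
    and are dropped with probability ``miss_prob``, in which case the previous
    correction state is retained.  Reproducible for a fixed seed.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if duration_s > max_recording_time(spec) * 3600.0:
        raise ValueError("duration exceeds the maximum recording time of the counter")
    rng = np.random.default_rng(seed)
    tick = spec.tick_s
    rate = 1.0 + drift_ppm * 1e-6
    quad = quad_ppm_per_hour * 1e-6 / 3600.0  # d(rate)/dt
    offset_sensor = rng.uniform(0.0, 1.0)     # different power-on instants [s]
    offset_rf = rng.uniform(0.0, 1.0)

    def slave(t: np.ndarray, offset: float) -> np.ndarray:
        return offset + rate * t + 0.5 * quad * t**2

    n = int(duration_s // spec.sync_period_s)
    t_b = np.arange(1, n + 1) * spec.sync_period_s
    jitter = rng.normal(0.0, jitter_ticks * tick, size=n)
    t_rx = t_b + np.abs(jitter)
    # processing delay: deterministic code path plus jitter-scale variability
    d_proc = 300e-6 + jitter_ticks * tick * rng.uniform(0.0, 1.0, size=n)

    t_mn = np.rint(t_b / tick).astype(np.int64)
    t_rf_rx = np.rint(slave(t_rx, offset_rf) / tick).astype(np.int64)
    t_rf_proc = np.rint(slave(t_rx + d_proc, offset_rf) / tick).astype(np.int64)
    t_sn_at_proc = np.rint(slave(t_rx + d_proc, offset_sensor) / tick).astype(np.int64)
    missed = rng.random(n) < miss_prob
    missed[0] = False  # the first beacon establishes the initial correction

    # retain the previous correction state on a miss
    keep = np.where(~missed, np.arange(n), 0)
    keep = np.maximum.accumulate(keep)
    return SyncLog(
        spec=spec,
        t_mn_sync=t_mn[keep],
        t_sn_sync=t_sn_at_proc[keep],
        dt_proc=(t_rf_proc - t_rf_rx)[keep],
        t_sn=np.rint(slave(t_b, offset_sensor) / tick).astype(np.int64),
        t_true_mn=t_mn.copy(),
        missed=missed,
        fs_hz=1.0 / spec.sync_period_s,
    )


@dataclass
class DriftReport:
    """Quadratic-fit drift indicators of one device."""

    p0_s: float
    p1_us_per_s: float          # divergence (linear slope of master - slave)
    p2: float
    linearity: float            # p2 / p1
    rmse_lin_s: float           # residual RMSE about the linear part of the fit
    abs_adjusted_divergence_us_per_s: float
    passed: bool = field(default=True)


def analyze_drift(log: SyncLog) -> DriftReport:
    """Fit the master-minus-slave clock deviation and grade the oscillator.

    The deviation ``(T_MN_sync - T_SN_sync) * tick`` is fit with a quadratic
    in time ``k / Fs``; the linear coefficient is the divergence, ``p2/p1``
    the linearity, and the RMSE is taken about the linear part of the same
    fit.  The adjusted divergence is the absolute slope of (corrected local
    time - true master time), which measures the residual error after the
    beacon-based timestamp adjustment.  A device fails at |divergence| >
    1 ms/s.
    """
    if log.n < 10:
        raise ValueError("need at least 10 sync samples")
    tick = log.spec.tick_s
    t = np.arange(1, log.n + 1) / log.fs_hz
    dev = (log.t_mn_sync - log.t_sn_sync).astype(float) * tick
    p2, p1, p0 = np.polyfit(t, dev, 2)
    rmse_lin = float(np.sqrt(np.mean((dev - (p1 * t + p0)) ** 2)))

    adj = (log.t_mn_sync + log.t_sn - log.t_sn_sync - log.dt_proc).astype(float)
    err = (adj - log.t_true_mn.astype(float)) * tick
    slope = np.polyfit(t, err, 1)[0]
    div_us = p1 * 1e6
    return DriftReport(
        p0_s=float(p0),
        p1_us_per_s=float(div_us),
        p2=float(p2),
        linearity=float(p2 / p1) if p1 != 0 else float("nan"),
        rmse_lin_s=rmse_lin,
        abs_adjusted_divergence_us_per_s=float(abs(slope) * 1e6),
        passed=bool(abs(div_us) <= FAIL_THRESHOLD_US_PER_S),
    )


def packet_error_rate(received: int, expected: int) -> float:
    """PER in %: 100 * (1 - received / expected)."""
    if expected <= 0:
        raise ValueError("expected packet count must be positive")
    return 100.0 * (1.0 - received / expected)


def rssi_per_correlation(rssi_dbm, per) -> float:
    """Pearson correlation of |RSSI| with PER (NaN for zero-variance input)."""
    r = np.abs(np.asarray(rssi_dbm, dtype=float))
    p = np.asarray(per, dtype=float)
    if r.shape != p.shape or r.size < 3:
        raise ValueError("need equal-length sequences of at least 3 values")
    if r.std() == 0 or p.std() == 0:
        return float("nan")
    return float(spstats.pearsonr(r, p).statistic)
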