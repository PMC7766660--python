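"""Synthetic treadmill-walking sessions for an FSR insole plus a thigh IMU.

The generator emulates the measurement chain of a four-sensor force-sensing-
resistor (FSR) insole — heel, big toe, and the first/fifth metatarsophalangeal
joints — feeding a first-order analog low-pass and a 12-bit ADC, together with
tri-axial thigh acceleration during walking.  Stride timing and stance-phase
statistics follow published treadmill reference values for slow walking
(1–4 km/h), so that segmentation and parameter-extraction algorithms can be
validated against exact ground truth.

Per-stride ground-reaction-force loading is modeled with raised-cosine
(half-cosine) loading windows per sensor: the heel loads first at heel strike,
the metatarsal sensors load mid-stance, and the toe loads last before push-off.
The terminal unloading of forefoot sensors is fast (tens of milliseconds), which
is what makes toe-off a sharp falling edge in the summed signal; heel unloading
in mid-stance is slow and deliberately stays below the derivative thresholds
used by the segmentation stage.  Amplitudes are not calibrated to force units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .segment import FsrRecord, GaitEvent, GaitEventList
from .activity import AccelTriax, ActivityMask

__all__ = [
    "GeneratorConfig",
    "SyntheticSession",
    "generate_grf_stride",
    "generate_walk_session",
    "lowpass_first_order",
    "SPEED_GRID_KMH",
    "STRIDE_TIME_REF_S",
    "PST_REF_PCT",
]

# Treadmill reference statistics for slow walking: mean stride time [s] and
# mean percentage stance time [%] on a 1.0–4.0 km/h speed grid.
SPEED_GRID_KMH = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0])
STRIDE_TIME_REF_S = np.array([2.05, 1.71, 1.49, 1.36, 1.26, 1.20, 1.14])
PST_REF_PCT = np.array([76.30, 72.37, 70.45, 69.22, 68.20, 67.40, 66.55])

# Relative per-channel peak loads (heel, toe, 5th MTP, 1st MTP); uncalibrated.
_CH_AMP = np.array([1.00, 0.60, 0.35, 0.35])
# Nominal full-load channel voltage [V] out of the resistive divider.
_V_SCALE = 2.2
# Residual shoe-contact voltage during swing [V].
_V_BASELINE = 0.15
# Elevated pre/post-gait contact level (normalized units of _V_SCALE).
_LEAD_LEVEL = 0.06


def lowpass_first_order(x: np.ndarray, fc: float, fs: float) -> np.ndarray:
    """First-order (RC) low-pass, exact pole mapping.

    ``y[k] = a*y[k-1] + (1-a)*x[k]`` with ``a = exp(-2*pi*fc/fs)``.  The state
    is primed with ``x[0]`` so a recording that starts on a plateau does not
    show a spurious start-up edge.
    """
    if fc <= 0 or fs <= 0:
        raise ValueError("fc and fs must be positive")
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected 1-D signal")
    a = np.exp(-2.0 * np.pi * fc / fs)
    y, _ = sps.lfilter([1.0 - a], [1.0, -a], x, zi=[a * x[0]])
    return y


def _smooth_step(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine transition 0 -> 1 over [center - width/2, center + width/2]."""
    u = np.clip((t - (center - width / 2.0)) / width, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * u)


def _stride_layout(stride_time: float, pst: float, fs: float) -> tuple[int, int, int, int]:
    """Sample counts of one stride: (n_total, n_stance, hs_index, edge_width)."""
    n = int(round(stride_time * fs))
    w = max(4, int(round(0.06 * fs)))
    s = int(round(pst / 100.0 * n))
    h0 = w // 2
    return n, s, h0, w


def generate_grf_stride(
    stride_time: float,
    pst: float,
    fs: float,
    *,
    double_peak: bool = False,
    artifact_amp: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One stride of per-sensor insole loading, shape ``(n, 4)``, in volts.

    Columns are (heel, toe, 5th MTP, 1st MTP).  The true heel strike is the
    onset of the initial rising edge (sample 0) and the true toe-off the onset
    of the terminal unloading edge (sample ``n_stance``), matching the edge
    semantics of the detector.  ``double_peak`` shifts heel unloading earlier
    so the summed signal
    shows the mid-stance amplitude dip seen at faster walking speeds.
    ``artifact_amp`` (fraction of the heel load) adds one broad, low-slope
    shoe-contact bump during swing.
    """
    if not np.isfinite([stride_time, pst, fs]).all():
        raise ValueError("stride parameters must be finite")
    if not (0.0 < pst < 100.0):
        raise ValueError(f"pst must lie in (0, 100), got {pst}")
    if stride_time <= 0 or fs <= 0:
        raise ValueError("stride_time and fs must be positive")
    n, s, h0, w = _stride_layout(stride_time, pst, fs)
    if n < 20:
        raise ValueError("stride_time * fs must be at least 20 samples")

    t = np.arange(n, dtype=float)
    heel_dn_c, heel_dn_w = (0.42, 0.50) if double_peak else (0.55, 0.50)

    heel = _smooth_step(t, h0, w) * (1.0 - _smooth_step(t, h0 + heel_dn_c * s, heel_dn_w * s))
    met5 = _smooth_step(t, h0 + 0.23 * s, 0.30 * s)
    met1 = _smooth_step(t, h0 + 0.50 * s, 0.24 * s)
    toe = _smooth_step(t, h0 + 0.775 * s, 0.35 * s)
    # Forefoot sensors unload together in the terminal fall centered on toe-off.
    term = 1.0 - _smooth_step(t, h0 + s, w)
    ch = np.stack([heel, toe * term, met5 * term, met1 * term], axis=1) * _CH_AMP

    if artifact_amp > 0.0:
        swing_lo = h0 + s + w  # first index safely past the terminal fall
        swing_hi = n - w
        if swing_hi - swing_lo > 8:
            r = rng if rng is not None else np.random.default_rng()
            bw = min(0.30 * fs, (swing_hi - swing_lo) * 0.8)
            c = r.uniform(swing_lo + bw / 2, swing_hi - bw / 2)
            bump = artifact_amp * _CH_AMP[0] * (
                _smooth_step(t, c - bw / 4, bw / 2) * (1.0 - _smooth_step(t, c + bw / 4, bw / 2))
            )
            ch[:, 0] += bump
    return ch * _V_SCALE


@dataclass
class GeneratorConfig:
    """All synthesis parameters of a walking session.

    ``speed_profile`` is a list of ``(speed_kmh, duration_s)`` blocks; speed 0
    means quiet standing.  Stride-time and stance-percentage means follow the
    treadmill reference grid and are interpolated piecewise-linearly in speed
    (clamped outside 1–4 km/h).
    """

    speed_profile: list[tuple[float, float]] = field(default_factory=lambda: [(3.0, 60.0)])
    stride_time_cv: float = 0.05
    pst_std_pct: float = 1.0
    stride_gain_cv: float = 0.08
    channel_gain_cv: float = 0.05
    fsr_fs: float = 100.0
    accel_fs: float = 100.0
    adc_bits: int = 12
    u_ref: float = 3.3
    lowpass_fc: float = 15.92
    fsr_noise_counts: float = 4.0
    accel_noise_g: float = 0.0015
    swing_artifact_amp: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.speed_profile:
            raise ValueError("speed_profile must contain at least one block")
        for v, d in self.speed_profile:
            if not (0.0 <= v <= 6.0):
                raise ValueError(f"speed {v} km/h outside [0, 6]")
            if d <= 0:
                raise ValueError("block durations must be positive")
        if self.fsr_fs <= 0 or self.accel_fs <= 0 or self.lowpass_fc <= 0:
            raise ValueError("sampling rates and corner frequency must be positive")
        if not (0 < self.stride_time_cv < 0.5):
            raise ValueError("stride_time_cv out of range")
        if self.adc_bits < 8 or self.adc_bits > 16:
            raise ValueError("adc_bits out of range")

    def stride_time_mean(self, speed_kmh: float) -> float:
        """Mean stride time [s] at a walking speed, clamped to the 1–4 km/h grid."""
        return float(np.interp(speed_kmh, SPEED_GRID_KMH, STRIDE_TIME_REF_S))

    def pst_mean(self, speed_kmh: float) -> float:
        """Mean percentage stance time [%] at a walking speed."""
        return float(np.interp(speed_kmh, SPEED_GRID_KMH, PST_REF_PCT))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["speed_profile"] = [list(b) for b in self.speed_profile]
        return d


@dataclass
class SyntheticSession:
    """A generated session together with its exact ground truth."""

    fsr: FsrRecord
    accel: AccelTriax
    truth_events: GaitEventList
    truth_activity: ActivityMask
    truth_stride_table: pd.DataFrame  # columns: start_s, stride_time_s, pst_pct, speed_kmh
    config: GeneratorConfig

    @property
    def duration_s(self) -> float:
        return self.fsr.n_samples / self.fsr.fs


def _quantize(volts: np.ndarray, bits: int, u_ref: float, noise_counts: float,
              rng: np.random.Generator) -> np.ndarray:
    full = 2**bits - 1
    counts = volts / u_ref * full
    if noise_counts > 0:
        counts = counts + rng.normal(0.0, noise_counts, size=counts.shape)
    return np.clip(np.rint(counts), 0, full).astype(np.int64)


def generate_walk_session(config: GeneratorConfig) -> SyntheticSession:
    """Synthesize a full session (FSR counts, thigh acceleration, ground truth).

    Walking blocks are composed stride by stride with multiplicative Gaussian
    stride-time jitter (cv = ``stride_time_cv``) and additive stance-percentage
    jitter; each block starts and ends with a short loaded lead-in/out so the
    first and last swing minima are well defined.  The per-channel voltages are
    low-pass filtered (first-order at ``lowpass_fc``) and quantized to the ADC
    grid; ground truth (events, per-stride table, activity intervals) is
    recorded exactly on the sample grid.  Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fsr_fs
    gain = float(np.clip(rng.normal(1.0, 0.08), 0.7, 1.3))

    chunks: list[np.ndarray] = []
    hs_times: list[float] = []
    to_times: list[float] = []
    stride_rows: list[tuple[float, float, float, float]] = []
    active: list[tuple[float, float]] = []
    n_cursor = 0  # running sample index

    lead_n = int(round(0.5 * fs))
    ramp_n = max(4, int(round(0.15 * fs)))

    def lead_chunk(falling: bool) -> np.ndarray:
        lvl = np.full(lead_n, _LEAD_LEVEL)
        ramp = 0.5 + 0.5 * np.cos(np.pi * np.arange(ramp_n) / (ramp_n - 1))
        if falling:
            lvl[-ramp_n:] = _LEAD_LEVEL * ramp
        else:
            lvl[:ramp_n] = _LEAD_LEVEL * ramp[::-1]
        return np.repeat(lvl[:, None], 4, axis=1) * _V_SCALE

    for speed, duration in config.speed_profile:
        block_n = int(round(duration * fs))
        if speed == 0.0:
            # quiet standing: constant partial load on all four sensors
            chunks.append(np.full((block_n, 4), 0.45 * _V_SCALE))
            n_cursor += block_n
            continue

        block_start = n_cursor
        st_mean = config.stride_time_mean(speed)
        pst_mean = config.pst_mean(speed)
        chunks.append(lead_chunk(falling=True))
        used = lead_n
        while True:
            z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
            st_l = st_mean * (1.0 + config.stride_time_cv * z)
            pst_l = float(np.clip(pst_mean + config.pst_std_pct * rng.standard_normal(), 55.0, 90.0))
            n_l, s_l, h0, _w = _stride_layout(st_l, pst_l, fs)
            if used + n_l > block_n - lead_n:
                break
            stride = generate_grf_stride(
                n_l / fs, pst_l, fs,
                double_peak=(speed >= 3.0),
                artifact_amp=config.swing_artifact_amp,
                rng=rng,
            )
            # stride-to-stride contact-pressure variability (scalar and per channel)
            g_stride = np.clip(rng.normal(1.0, config.stride_gain_cv), 0.6, 1.4)
            g_ch = np.clip(rng.normal(1.0, config.channel_gain_cv, size=4), 0.7, 1.3)
            stride = stride * (g_stride * g_ch)
            chunks.append(stride)
            hs = (n_cursor + used) / fs  # rising-edge onset
            hs_times.append(hs)
            to_times.append(hs + s_l / fs)
            stride_rows.append((hs, n_l / fs, 100.0 * s_l / n_l, speed))
            used += n_l
        chunks.append(lead_chunk(falling=False))
        used += lead_n
        if used < block_n:
            chunks.append(np.full((block_n - used, 4), _LEAD_LEVEL * _V_SCALE))
        n_cursor += block_n
        active.append((block_start / fs, n_cursor / fs))

    volts = np.concatenate(chunks, axis=0) * gain + _V_BASELINE
    n_total = volts.shape[0]
    filt = np.column_stack(
        [lowpass_first_order(volts[:, i], config.lowpass_fc, fs) for i in range(4)]
    )
    counts = _quantize(filt, config.adc_bits, config.u_ref, config.fsr_noise_counts, rng)
    fsr = FsrRecord(fs=fs, channels=counts.astype(float), start_time=0.0)

    accel = _thigh_accel(config, stride_rows, n_total / fs, rng)

    events = sorted(
        [GaitEvent("HS", t, int(round(t * fs))) for t in hs_times]
        + [GaitEvent("TO", t, int(round(t * fs))) for t in to_times],
        key=lambda e: e.time,
    )
    truth_events = GaitEventList(events)
    truth_activity = ActivityMask(_merge_intervals(active))
    table = pd.DataFrame(stride_rows, columns=["start_s", "stride_time_s", "pst_pct", "speed_kmh"])
    return SyntheticSession(fsr, accel, truth_events, truth_activity, table, config)


def _merge_intervals(iv: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for a, b in sorted(iv):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _thigh_accel(config: GeneratorConfig, stride_rows: list, duration_s: float,
                 rng: np.random.Generator) -> AccelTriax:
    """Thigh acceleration: gravity at rest, stride-locked oscillation while walking.

    The oscillation amplitude grows with speed so that the peak magnitude
    approaches +/-3.5 g at 4 km/h, matching the dynamic range observed at the
    thigh during treadmill walking.
    """
    fs = config.accel_fs
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = np.zeros(n)
    amp = np.zeros(n)
    for start, st, _pst, speed in stride_rows:
        i0 = int(np.ceil(start * fs))
        i1 = min(n, int(np.ceil((start + st) * fs)))
        if i1 <= i0:
            continue
        phase[i0:i1] = (t[i0:i1] - start) / st
        amp[i0:i1] = min(0.35 + 0.5 * speed, 2.5)
    ax = 0.45 * amp * np.sin(2 * np.pi * phase + 1.2)
    ay = 0.35 * amp * np.sin(4 * np.pi * phase + 0.4)
    az = 1.0 + amp * (0.55 * np.sin(2 * np.pi * phase) + 0.45 * np.sin(4 * np.pi * phase + 0.9))
    az[amp == 0] = 1.0
    noise = rng.normal(0.0, config.accel_noise_g, size=(3, n))
    return AccelTriax(fs=fs, ax=ax + noise[0], ay=ay + noise[1], az=az + noise[2])


def save_session(session: SyntheticSession, out_dir) -> dict:
    """Write a session to CSV files plus a JSON sidecar; returns the paths."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fsr = session.fsr
    fsr_df = pd.DataFrame(fsr.channels.astype(int), columns=["fsr1", "fsr2", "fsr3", "fsr4"])
    fsr_df.insert(0, "time_s", np.arange(fsr.n_samples) / fsr.fs + fsr.start_time)
    fsr_path = out / "fsr.csv"
    fsr_df.to_csv(fsr_path, index=False)

    acc = session.accel
    acc_df = pd.DataFrame({
        "time_s": np.arange(len(acc.ax)) / acc.fs,
        "ax_g": acc.ax, "ay_g": acc.ay, "az_g": acc.az,
    })
    accel_path = out / "accel.csv"
    acc_df.to_csv(accel_path, index=False)

    ev_df = pd.DataFrame(
        [(e.kind, e.time) for e in session.truth_events.events], columns=["event", "time_s"]
    )
    events_path = out / "truth_events.csv"
    ev_df.to_csv(events_path, index=False)

    sidecar = out / "session.json"
    sidecar.write_text(json.dumps({"config": session.config.to_dict()}, indent=2))
    return {"fsr": str(fsr_path), "accel": str(accel_path),
            "events": str(events_path), "sidecar": str(sidecar)}
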