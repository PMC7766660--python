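"""Heel-strike / toe-off detection from summed FSR insole signals.

The summed (arithmetic-mean) four-channel FSR signal is approximately a
band-limited rectangular wave: high during stance, near baseline during swing.
Gait events are therefore edges of this wave.  Detection proceeds in three
steps:

1. derive derivative thresholds from the recording itself — the rising
   threshold is 1/6 of the maximum of the first-difference signal and the
   falling threshold 1/7 of its minimum (the falling edge is steeper); the
   empirical CDF of the difference signal, whose two turning points separate
   edge samples from plateau samples, is reported as a diagnostic of this
   choice;
2. locate swing-phase minima of the summed signal with a minimum peak
   separation of 0.7 s;
3. from every swing minimum, search backward for the nearest contiguous run of
   sub-threshold (falling) differences — its first sample is the toe-off — and
   forward for the first supra-threshold (rising) difference — the heel strike.

Events whose search leaves the recording are flagged as boundary-partial and
are excluded from stride statistics downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "FsrRecord",
    "FsrSumSeries",
    "SegmentationThresholds",
    "GaitEvent",
    "GaitEventList",
    "sum_fsr",
    "derive_thresholds",
    "find_swing_minima",
    "detect_events",
    "segment_record",
]


@dataclass
class FsrRecord:
    """Uniformly sampled four-channel insole recording.

    ``channels`` has shape ``(n, 4)`` (heel, toe, 5th MTP, 1st MTP), in ADC
    counts or any common per-channel unit.
    """

    fs: float
    channels: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[1] != 4:
            raise ValueError("channels must be an (n, 4) array")
        if not np.isfinite(self.channels).all():
            raise ValueError("channel values must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[0]


@dataclass
class FsrSumSeries:
    """Summed FSR signal and its first difference (per-sample units)."""

    fs: float
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.diff = np.diff(self.values)


def sum_fsr(record: FsrRecord) -> FsrSumSeries:
    """Arithmetic mean of the four FSR channels at every sample."""
    return FsrSumSeries(
        fs=record.fs, values=record.channels.mean(axis=1), start_time=record.start_time
    )


@dataclass
class SegmentationThresholds:
    """Derivative thresholds plus the eCDF turning-point diagnostic.

    ``ecdf_turning_points`` holds the normalized difference amplitudes (0 maps
    to the most negative difference, 1 to the most positive) of the points on
    the normalized eCDF closest to the corners (1, 1) and (0, 0).
    """

    thr_rising: float
    thr_falling: float
    ecdf_turning_points: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        if not (self.thr_rising > 0.0 > self.thr_falling):
            raise ValueError("need thr_rising > 0 > thr_falling")


def _ecdf_turning_points(diff: np.ndarray) -> tuple[float, float]:
    x = np.sort(diff)
    lo, hi = x[0], x[-1]
    xn = (x - lo) / (hi - lo)
    yn = np.arange(1, x.size + 1) / x.size
    d_plus = np.hypot(xn - 1.0, yn - 1.0)
    d_minus = np.hypot(xn, yn)
    return float(xn[np.argmin(d_plus)]), float(xn[np.argmin(d_minus)])


def derive_thresholds(
    sum_series: FsrSumSeries,
    rising_fraction: float = 1.0 / 6.0,
    falling_fraction: float = 1.0 / 7.0,
) -> SegmentationThresholds:
    """Per-recording edge thresholds from the extrema of the difference signal.

    ``thr_rising = rising_fraction * max(diff)`` and
    ``thr_falling = falling_fraction * min(diff)``.  The integer fractions 1/6
    and 1/7 are fixed rounded values originally obtained from the eCDF
    turning-point analysis, which is recomputed here as a diagnostic.
    """
    d = sum_series.diff
    if d.size == 0 or not (d.max() > 0.0 > d.min()):
        raise ValueError("difference signal is degenerate (needs max > 0 > min)")
    return SegmentationThresholds(
        thr_rising=rising_fraction * float(d.max()),
        thr_falling=falling_fraction * float(d.min()),
        ecdf_turning_points=_ecdf_turning_points(d),
    )


def find_swing_minima(sum_series: FsrSumSeries, min_distance: float = 0.7) -> np.ndarray:
    """Local minima of the summed signal separated by at least ``min_distance`` s.

    When two candidate minima violate the separation, the deeper one is kept.
    Plateau minima (exactly flat swing phases) are reported at their midpoint.
    """
    d = int(round(min_distance * sum_series.fs))
    if d < 1:
        raise ValueError("fs * min_distance must be at least 1 sample")
    v = sum_series.values
    if v.size < d:
        return np.array([], dtype=int)
    idx, _ = sps.find_peaks(-v, distance=d)
    return idx


@dataclass(frozen=True)
class GaitEvent:
    kind: str  # "HS" or "TO"
    time: float  # seconds
    index: int  # sample index into the summed signal
    partial: bool = False  # touches the recording boundary; excluded from stats


@dataclass
class GaitEventList:
    """Time-ordered, alternating heel-strike/toe-off events."""

    events: list[GaitEvent] = field(default_factory=list)
    status: str = "ok"

    def times(self, kind: str | None = None, include_partial: bool = False) -> np.ndarray:
        return np.array([
            e.time for e in self.events
            if (kind is None or e.kind == kind) and (include_partial or not e.partial)
        ])

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def _backward_toe_off(diff: np.ndarray, start: int, thr_falling: float) -> tuple[int, bool] | None:
    """First sample of the nearest falling run at or before ``start``."""
    j = min(start, diff.size - 1)
    while j >= 0 and diff[j] > thr_falling:
        j -= 1
    if j < 0:
        return None
    while j - 1 >= 0 and diff[j - 1] <= thr_falling:
        j -= 1
    return j, j == 0


def _forward_heel_strike(diff: np.ndarray, start: int, thr_rising: float) -> tuple[int, bool] | None:
    k = max(start, 0)
    while k < diff.size and diff[k] < thr_rising:
        k += 1
    if k >= diff.size:
        return None
    return k, k == diff.size - 1


def detect_events(
    sum_series: FsrSumSeries,
    thresholds: SegmentationThresholds,
    minima: np.ndarray,
    include_boundaries: bool = True,
) -> GaitEventList:
    """Locate toe-off and heel-strike events around each swing minimum.

    For every minimum, toe-off is the first sample of the nearest contiguous
    run of differences at or below the falling threshold searching backward,
    and heel strike is the first difference at or above the rising threshold
    searching forward.  With ``include_boundaries`` the recording start acts as
    a virtual minimum for the forward search and the recording end for the
    backward search, so the first heel strike and last toe-off are found even
    when no baseline minimum flanks them.  Duplicate finds are merged and
    strict HS/TO alternation is enforced (the earlier of two same-kind events
    is kept).
    """
    d = sum_series.diff
    fs, t0 = sum_series.fs, sum_series.start_time
    found: set[tuple[str, int]] = set()
    raw: list[GaitEvent] = []

    def add(kind: str, idx: int, partial: bool) -> None:
        if (kind, idx) not in found:
            found.add((kind, idx))
            raw.append(GaitEvent(kind, t0 + idx / fs, idx, partial))

    starts: list[tuple[int, bool, bool]] = [(int(m), True, True) for m in np.sort(minima)]
    if include_boundaries and d.size:
        starts.insert(0, (0, False, True))        # forward only
        starts.append((d.size - 1, True, False))  # backward only

    for m, do_back, do_fwd in starts:
        if do_back:
            hit = _backward_toe_off(d, m - 1, thresholds.thr_falling)
            if hit is not None:
                add("TO", hit[0], hit[1])
        if do_fwd:
            hit = _forward_heel_strike(d, m, thresholds.thr_rising)
            if hit is not None:
                add("HS", hit[0], hit[1])

    raw.sort(key=lambda e: (e.index, e.kind))
    merged: list[GaitEvent] = []
    for e in raw:
        if merged and merged[-1].kind == e.kind:
            continue  # keep the earlier of two same-kind events
        merged.append(e)

    status = "ok"
    if not merged:
        status = "no-events"
        warnings.warn("no threshold crossings found for any swing minimum", stacklevel=2)
    return GaitEventList(merged, status=status)


def segment_record(
    record: FsrRecord,
    min_distance: float = 0.7,
    rising_fraction: float = 1.0 / 6.0,
    falling_fraction: float = 1.0 / 7.0,
) -> tuple[GaitEventList, SegmentationThresholds]:
    """Full segmentation pipeline: sum -> thresholds -> minima -> events."""
    s = sum_fsr(record)
    thr = derive_thresholds(s, rising_fraction, falling_fraction)
    minima = find_swing_minima(s, min_distance)
    return detect_events(s, thr, minima), thr
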