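"""Per-stride gait parameters and validation statistics.

A stride is one full gait cycle of one foot.  Stride time is the interval
between consecutive same-kind events, ``ST[l] = T_HS[l+1] - T_HS[l]`` (heel
strikes are the default basis, being the more reliably detected landmark);
percentage stance time relates the stance duration to the whole cycle,
``PST[l] = (T_TO[l] - T_HS[l]) / ST[l] * 100``.  Agreement with a reference
system is quantified by stride-count accuracy, RMSE, Bland–Altman bias and
limits of agreement, and Pearson correlation.  Stride-shape reproducibility is
summarized by a time-normalized mean/std morphology and its coefficient of
variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .segment import FsrSumSeries, GaitEventList

__all__ = [
    "StrideMetrics",
    "ValidationStats",
    "MorphologyStats",
    "stride_times",
    "percentage_stance",
    "stride_count_accuracy",
    "rmse",
    "stride_morphology",
    "agreement_stats",
    "stride_metrics",
    "per_minute_summary",
]


def stride_times(events: GaitEventList, basis: str = "HS") -> np.ndarray:
    """Consecutive differences of same-kind event times (boundary-partial excluded)."""
    if basis not in ("HS", "TO"):
        raise ValueError("basis must be 'HS' or 'TO'")
    t = events.times(basis)
    return np.diff(t) if t.size >= 2 else np.array([])


def percentage_stance(events: GaitEventList) -> np.ndarray:
    """PST[l] = (T_TO[l] - T_HS[l]) / (T_HS[l+1] - T_HS[l]) * 100 per stride.

    Requires a strictly alternating event list; leading toe-offs are skipped.
    """
    ev = [e for e in events if not e.partial]
    for a, b in zip(ev, ev[1:]):
        if a.kind == b.kind:
            raise ValueError("event list must alternate HS/TO")
    while ev and ev[0].kind != "HS":
        ev = ev[1:]
    out = []
    for i in range(0, len(ev) - 2, 2):
        hs0, to0, hs1 = ev[i], ev[i + 1], ev[i + 2]
        out.append(100.0 * (to0.time - hs0.time) / (hs1.time - hs0.time))
    return np.array(out)


def stride_count_accuracy(nos_test: int, nos_ref: int) -> float:
    """Detection accuracy in %: 100 * (1 - |NoS_ref - NoS_test| / NoS_ref)."""
    if nos_ref <= 0:
        raise ValueError("reference stride count must be positive")
    return 100.0 * (1.0 - abs(nos_ref - nos_test) / nos_ref)


def rmse(y_test, y_ref) -> float:
    """Root-mean-square error between two equal-length sequences."""
    a = np.asarray(y_test, dtype=float)
    b = np.asarray(y_ref, dtype=float)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    if a.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class MorphologyStats:
    """Time-normalized stride-shape statistics across cycles."""

    mean_curve: np.ndarray
    std_curve: np.ndarray
    cov: float
    n_cycles: int


def stride_morphology(
    sum_series: FsrSumSeries, events: GaitEventList, n_points: int = 100
) -> MorphologyStats:
    """Mean/std curves over HS->HS cycles resampled to ``n_points``.

    The coefficient of variation is the pointwise std/mean ratio averaged over
    the portion of normalized time where the mean curve is positive.
    """
    hs = events.times("HS")
    if hs.size < 3:
        raise ValueError("need at least 2 complete HS->HS cycles")
    fs, t0 = sum_series.fs, sum_series.start_time
    grid = np.linspace(0.0, 1.0, n_points, endpoint=False)
    cycles = []
    for a, b in zip(hs, hs[1:]):
        i0, i1 = int(round((a - t0) * fs)), int(round((b - t0) * fs))
        seg = sum_series.values[i0:i1]
        if seg.size < 2:
            continue
        cycles.append(np.interp(grid * (seg.size - 1), np.arange(seg.size), seg))
    if len(cycles) < 2:
        raise ValueError("need at least 2 complete HS->HS cycles")
    arr = np.vstack(cycles)
    mean_c = arr.mean(axis=0)
    std_c = arr.std(axis=0, ddof=1)
    pos = mean_c > 0
    cov = float(np.mean(std_c[pos] / mean_c[pos])) if pos.any() else float("nan")
    return MorphologyStats(mean_c, std_c, cov, arr.shape[0])


def agreement_stats(x, y) -> "ValidationStats":
    """Bland–Altman bias/limits of agreement plus Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length sequences of at least 3 values")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if x.std() == 0 or y.std() == 0:
        r = float("nan")
    else:
        r = float(spstats.pearsonr(x, y).statistic)
    return ValidationStats(
        accuracy=float("nan"),
        rmse=rmse(x, y),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        pearson_r=r,
    )


@dataclass
class ValidationStats:
    accuracy: float      # stride-count detection accuracy [%]
    rmse: float
    bias: float
    loa_low: float
    loa_high: float
    pearson_r: float


@dataclass
class StrideMetrics:
    """Aggregated gait parameters of one recording (HS basis by default)."""

    stride_times_s: np.ndarray
    pst_pct: np.ndarray
    nos: int                 # number of strides = detected HS count
    cadence_spm: float       # strides per minute
    mean_stride_time_s: float
    basis: str = "HS"


def stride_metrics(events: GaitEventList, basis: str = "HS") -> StrideMetrics:
    st = stride_times(events, basis)
    hs = events.times("HS")
    nos = int(hs.size)
    mean_st = float(st.mean()) if st.size else float("nan")
    cadence = 60.0 / mean_st if st.size and mean_st > 0 else float("nan")
    try:
        pst = percentage_stance(events)
    except ValueError:
        pst = np.array([])
    return StrideMetrics(st, pst, nos, cadence, mean_st, basis)


def per_minute_summary(events: GaitEventList, bin_s: float = 60.0) -> list[dict]:
    """Mean stride time, PST and cadence aggregated over fixed time bins.

    A stride is assigned to the bin that contains its starting heel strike.
    """
    hs = events.times("HS")
    if hs.size < 2:
        return []
    st = np.diff(hs)
    try:
        pst = percentage_stance(events)
    except ValueError:
        pst = np.array([])
    rows = []
    t_end = hs[-1]
    n_bins = max(1, math.ceil(t_end / bin_s))
    for i in range(n_bins):
        lo, hi = i * bin_s, (i + 1) * bin_s
        sel = (hs[:-1] >= lo) & (hs[:-1] < hi)
        if not sel.any():
            continue
        sel_pst = sel[: pst.size] if pst.size else np.array([], dtype=bool)
        rows.append({
            "bin_start_s": lo,
            "bin_end_s": hi,
            "n_strides": int(sel.sum()),
            "mean_stride_time_s": float(st[sel].mean()),
            "cadence_spm": 60.0 / float(st[sel].mean()),
            "mean_pst_pct": float(pst[sel_pst].mean()) if pst.size and sel_pst.any() else float("nan"),
        })
    return rows
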