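"""End-to-end processing: acceleration-gated segmentation and gait reporting.

The pipeline mirrors how a long-term recording is analyzed: walking bouts are
first located in the thigh acceleration, the FSR segmentation is then applied
only within those active intervals (thresholds are derived per bout), and
per-minute gait parameters are aggregated from the detected events.  The JSON
report carries the configuration hash for provenance.
"""

from __future__ import annotations

import logging

from . import params as gp
from .activity import AccelTriax, ActivityMask, detect_activity, signal_vector_magnitude
from .io import PipelineConfig
from .segment import (
    FsrRecord, FsrSumSeries, GaitEventList, derive_thresholds, detect_events,
    find_swing_minima, sum_fsr,
)

__all__ = ["run_pipeline", "segment_active_intervals"]

log = logging.getLogger("insolegait")


def segment_active_intervals(
    record: FsrRecord, mask: ActivityMask, config: PipelineConfig
) -> GaitEventList:
    """Run the event detector independently on every active interval."""
    s = sum_fsr(record)
    all_events = []
    for start_s, end_s in mask.intervals:
        i0 = max(0, int(round((start_s - record.start_time) * record.fs)))
        i1 = min(record.n_samples, int(round((end_s - record.start_time) * record.fs)))
        if i1 - i0 < int(config.min_peak_distance_s * record.fs):
            continue
        seg = FsrSumSeries(fs=record.fs, values=s.values[i0:i1],
                           start_time=record.start_time + i0 / record.fs)
        try:
            thr = derive_thresholds(seg, config.rising_fraction, config.falling_fraction)
        except ValueError:
            log.info("interval %.1f-%.1f s: degenerate signal, skipped", start_s, end_s)
            continue
        minima = find_swing_minima(seg, config.min_peak_distance_s)
        ev = detect_events(seg, thr, minima)
        log.info(
            "interval %.1f-%.1f s: thr_rising=%.3g thr_falling=%.3g events=%d",
            start_s, end_s, thr.thr_rising, thr.thr_falling, len(ev),
        )
        all_events.extend(ev.events)
    merged = []
    for e in sorted(all_events, key=lambda e: e.time):
        if merged and merged[-1].kind == e.kind:
            continue
        merged.append(e)
    return GaitEventList(merged)


def run_pipeline(
    record: FsrRecord,
    accel: AccelTriax,
    config: PipelineConfig,
    ref_events: GaitEventList | None = None,
) -> dict:
    """Full analysis of one recording; returns a JSON-serializable report."""
    svm = signal_vector_magnitude(accel)
    _profile, mask = detect_activity(
        svm, accel.fs,
        window_s=config.activity_window_s,
        threshold_g=config.activity_threshold_g,
        median_len=config.activity_median_len,
        opening_len=config.activity_opening_len,
    )
    events = segment_active_intervals(record, mask, config)
    n_partial = sum(1 for e in events if e.partial)
    metrics = gp.stride_metrics(events)
    per_minute = gp.per_minute_summary(events, config.bin_s)
    log.info("detected %d events (%d partial), %d strides", len(events), n_partial, metrics.nos)

    report = {
        "config_hash": config.hash(),
        "activity": {"intervals": [list(iv) for iv in mask.intervals],
                     "total_active_s": mask.total_s()},
        "events": {
            "n_events": len(events),
            "n_partial": n_partial,
            "n_strides": metrics.nos,
            "list": [
                {"event": e.kind, "time_s": e.time, "sample_index": e.index,
                 "partial": e.partial} for e in events
            ],
        },
        "per_minute": per_minute,
        "validation": None,
    }
    if ref_events is not None:
        nos_ref = int(ref_events.times("HS").size)
        st_test = gp.stride_times(events)
        st_ref = gp.stride_times(ref_events)
        validation: dict = {
            "accuracy_pct": gp.stride_count_accuracy(metrics.nos, nos_ref) if nos_ref else None,
        }
        n = min(st_test.size, st_ref.size)
        if n >= 3:
            ag = gp.agreement_stats(st_test[:n], st_ref[:n])
            validation.update(
                stride_time_rmse_s=ag.rmse, bias_s=ag.bias,
                loa_low_s=ag.loa_low, loa_high_s=ag.loa_high, pearson_r=ag.pearson_r,
            )
        report["validation"] = validation
    return report
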