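"""CSV/JSON readers and writers and the serializable pipeline configuration.

All files are plain comma-separated text with a mandatory header row and dot
decimals.  Times in files are seconds from recording start; synchronization
logs keep integer ticks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import AccelTriax, ActivityMask
from .segment import FsrRecord, GaitEvent, GaitEventList

__all__ = [
    "PipelineConfig",
    "read_fsr_csv",
    "read_accel_csv",
    "write_events_csv",
    "read_events_csv",
    "write_activity_csv",
    "write_json",
]


@dataclass
class PipelineConfig:
    """End-to-end processing parameters; JSON round-trips losslessly."""

    fsr_fs: float = 100.0
    accel_fs: float = 100.0
    min_peak_distance_s: float = 0.7
    rising_fraction: float = 1.0 / 6.0
    falling_fraction: float = 1.0 / 7.0
    activity_threshold_g: float = 0.1
    activity_window_s: float = 1.0
    activity_median_len: int = 5
    activity_opening_len: int = 10
    bin_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fsr_fs <= 0 or self.accel_fs <= 0:
            raise ValueError("sampling rates must be positive")
        if self.min_peak_distance_s <= 0:
            raise ValueError("min_peak_distance must be positive")
        if not (0 < self.rising_fraction <= 1 and 0 < self.falling_fraction <= 1):
            raise ValueError("threshold fractions must lie in (0, 1]")
        if self.bin_s <= 0 or self.activity_window_s <= 0:
            raise ValueError("window lengths must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_fsr_csv(path, fs: float | None = None) -> FsrRecord:
    """Read an FSR recording (columns time_s, fsr1..fsr4).

    ``fs`` overrides the rate inferred from the time column; a mismatch of
    more than 1 % raises.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "fsr1", "fsr2", "fsr3", "fsr4"], path)
    inferred = _infer_fs(df["time_s"].to_numpy(), path)
    if fs is None:
        fs = inferred
    elif inferred is not None and abs(fs - inferred) / fs > 0.01:
        raise ValueError(f"{path}: configured fs {fs} Hz disagrees with file ({inferred:.3f} Hz)")
    return FsrRecord(
        fs=fs,
        channels=df[["fsr1", "fsr2", "fsr3", "fsr4"]].to_numpy(dtype=float),
        start_time=float(df["time_s"].iloc[0]),
    )


def read_accel_csv(path, fs: float | None = None) -> AccelTriax:
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "ax_g", "ay_g", "az_g"], path)
    inferred = _infer_fs(df["time_s"].to_numpy(), path)
    if fs is None:
        fs = inferred
    elif inferred is not None and abs(fs - inferred) / fs > 0.01:
        raise ValueError(f"{path}: configured fs {fs} Hz disagrees with file ({inferred:.3f} Hz)")
    return AccelTriax(fs=fs, ax=df["ax_g"].to_numpy(), ay=df["ay_g"].to_numpy(),
                      az=df["az_g"].to_numpy())


def _infer_fs(t: np.ndarray, path) -> float | None:
    if t.size < 2:
        return None
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time_s column must be strictly increasing")
    return 1.0 / float(np.median(dt))


def write_events_csv(events: GaitEventList, path) -> None:
    pd.DataFrame(
        [(e.kind, e.time, e.index, int(e.partial)) for e in events],
        columns=["event", "time_s", "sample_index", "partial"],
    ).to_csv(path, index=False)


def read_events_csv(path) -> GaitEventList:
    df = pd.read_csv(path)
    _require_columns(df, ["event", "time_s"], path)
    evs = []
    for _, row in df.iterrows():
        evs.append(GaitEvent(
            str(row["event"]), float(row["time_s"]),
            int(row["sample_index"]) if "sample_index" in df.columns else -1,
            bool(row["partial"]) if "partial" in df.columns else False,
        ))
    return GaitEventList(sorted(evs, key=lambda e: e.time))


def write_activity_csv(mask: ActivityMask, path) -> None:
    pd.DataFrame(mask.intervals, columns=["start_s", "end_s"]).to_csv(path, index=False)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
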