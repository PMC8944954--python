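"""Domain containers and file I/O shared by every analysis stage.

Signals are stored as delimited text (one column per channel, header row of
channel ids) plus a JSON sidecar declaring the sampling rate and the
channel->region map.  All timestamps are seconds, zero-based from trace
start; ictal windows are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

REGIONS = ("CA3", "CA1", "SUB", "CTX", "DG", "other")

__all__ = [
    "REGIONS",
    "SignalTrace",
    "EventTrain",
    "IctalLabelSet",
    "AnalysisConfig",
    "read_signal",
    "write_signal",
    "read_events",
    "write_events",
    "read_labels",
    "write_labels",
    "resample",
    "substream_seed",
]


def substream_seed(master: int, *keys: int | str) -> int:
    """Derive a deterministic 31-bit sub-seed from a master seed.

    Named sub-streams keep each synthesis/stimulation component stable when
    another component is regenerated.  String keys are hashed with CRC32 so
    the mapping is reproducible across sessions.
    """
    ints = [int(master) & 0xFFFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SignalTrace:
    """One channel of extracellular field potential.

    samples are in microvolts; ``fs`` is the sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float
    channel_id: str = "ch0"
    region: str = "other"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class EventTrain:
    """Sorted event timestamps (s); IEIs are the first differences."""

    times: np.ndarray
    source: str = "detected"  # detected | synthetic | stimulus

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must be non-negative")
        if self.source not in ("detected", "synthetic", "stimulus"):
            raise ValueError(f"unknown source {self.source!r}")

    def __len__(self) -> int:
        return self.times.size

    def iei(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class IctalLabelSet:
    """Labelled ictal windows [(onset, offset)] within an observation window.

    ``mode`` selects the t_TOT convention of the ictal time-percentage:
    "stim" uses the protocol duration ``t_tot``; "ctrl" uses the span from
    the first onset to the last offset.
    """

    windows: list[tuple[float, float]]
    t_tot: float
    mode: str = "ctrl"  # stim | ctrl

    def __post_init__(self) -> None:
        self.windows = [(float(a), float(b)) for a, b in self.windows]
        if self.mode not in ("stim", "ctrl"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.t_tot > 0:
            raise ValueError("t_tot must be positive")
        last = -np.inf
        for onset, offset in self.windows:
            if not onset < offset:
                raise ValueError("each window needs onset < offset")
            if onset < last:
                raise ValueError("windows must be sorted and non-overlapping")
            last = offset
        if self.total_duration() > self.t_tot + 1e-9:
            raise ValueError("summed window duration exceeds t_tot")

    def __len__(self) -> int:
        return len(self.windows)

    def total_duration(self) -> float:
        return float(sum(b - a for a, b in self.windows))


@dataclass
class AnalysisConfig:
    """Pipeline-wide settings with the defaults used throughout the study."""

    seed: int = 0
    lowpass_cutoff: float = 200.0
    filter_order: int = 3
    threshold_fraction: float = 0.5
    refractory: float = 0.1
    analysis_fs: float = 512.0
    wavelet: str = "db4"
    baseline_band: tuple[float, float] = (1.0, 4.0)
    ictal_band: tuple[float, float] = (10.0, 40.0)
    threshold_k: float = 5.0
    cluster_gap: float = 2.0
    ks_alpha: float = 0.05
    step: float = 600.0

    def __post_init__(self) -> None:
        for name in ("lowpass_cutoff", "filter_order", "threshold_fraction",
                     "refractory", "analysis_fs", "threshold_k",
                     "cluster_gap", "step"):
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.ks_alpha < 1:
            raise ValueError("ks_alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        data = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
        return cls(**data)


# ---------------------------------------------------------------------------
# File I/O


def read_signal(path_csv: str | Path, path_meta: str | Path) -> dict[str, SignalTrace]:
    """Read a multichannel CSV + JSON sidecar into one trace per channel."""
    meta = json.loads(Path(path_meta).read_text())
    if "fs" not in meta:
        raise ValueError("metadata incomplete: missing 'fs'")
    fs = float(meta["fs"])
    regions = meta.get("channels", {})
    t0 = float(meta.get("t0", 0.0))
    try:
        frame = pd.read_csv(path_csv, float_precision="round_trip")
        frame = frame.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric sample in {path_csv}: {exc}") from exc
    if frame.isna().any().any():
        bad = int(frame.isna().any(axis=1).idxmax()) + 2  # header + 1-based
        raise ValueError(f"non-numeric sample at row {bad} of {path_csv}")
    traces = {}
    for col in frame.columns:
        traces[str(col)] = SignalTrace(
            samples=frame[col].to_numpy(dtype=float),
            fs=fs,
            channel_id=str(col),
            region=regions.get(str(col), "other"),
            t0=t0,
        )
    return traces


def write_signal(traces: dict[str, SignalTrace] | Sequence[SignalTrace],
                 path_csv: str | Path, path_meta: str | Path) -> None:
    if not isinstance(traces, dict):
        traces = {t.channel_id: t for t in traces}
    if not traces:
        raise ValueError("no traces to write")
    fs = {t.fs for t in traces.values()}
    t0 = {t.t0 for t in traces.values()}
    if len(fs) != 1 or len(t0) != 1:
        raise ValueError("all channels must share fs and t0")
    frame = pd.DataFrame({cid: t.samples for cid, t in traces.items()})
    frame.to_csv(path_csv, index=False, float_format="%.17g")
    meta = {
        "fs": fs.pop(),
        "t0": t0.pop(),
        "channels": {cid: t.region for cid, t in traces.items()},
    }
    Path(path_meta).write_text(json.dumps(meta, indent=1))


def read_events(path: str | Path, source: str = "detected") -> EventTrain:
    return EventTrain(times=np.asarray(json.loads(Path(path).read_text()), dtype=float),
                      source=source)


def write_events(train: EventTrain, path: str | Path) -> None:
    Path(path).write_text(json.dumps([float(t) for t in train.times]))


def read_labels(path: str | Path) -> IctalLabelSet:
    data = json.loads(Path(path).read_text())
    return IctalLabelSet(windows=[tuple(w) for w in data["windows"]],
                         t_tot=data["t_tot"], mode=data.get("mode", "ctrl"))


def write_labels(labels: IctalLabelSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "windows": [[a, b] for a, b in labels.windows],
        "t_tot": labels.t_tot,
        "mode": labels.mode,
    }, indent=1))


# ---------------------------------------------------------------------------
# Resampling


def resample(trace: SignalTrace, fs_new: float) -> SignalTrace:
    """Rational-ratio polyphase resampling with built-in anti-alias filtering.

    Duration is preserved to within one output sample period; the dyadic
    wavelet stage relies on this to map its analysis bands onto a 512 Hz
    time base.
    """
    if not fs_new > 0:
        raise ValueError("fs_new must be positive")
    if fs_new == trace.fs:
        return replace(trace, samples=trace.samples.copy())
    frac = Fraction(fs_new / trace.fs).limit_denominator(10_000)
    out = sps.resample_poly(trace.samples, frac.numerator, frac.denominator)
    return replace(trace, samples=out, fs=fs_new)
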