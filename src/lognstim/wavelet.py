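"""Wavelet-based ictal detection and ictal-state metrics.

Seizure-like (ictal) discharges are detected on a multiresolution
analysis (MRA) of the trace using the Daubechies-4 wavelet (stationary /
undecimated variant, so components stay aligned to the original time
base): the 1-4 Hz
component provides baseline statistics (Gaussian moments over a
user-selected event-free window) and the 10-40 Hz component is thresholded
at mu +/- k*sigma (k = 5) of that baseline; suprathreshold samples are
clustered into windows whose onset/offset are the first/last crossing.
No minimum-duration cut-off is applied, so short entrained bursts count as
ictal time.

The dyadic detail level l at sampling rate fs nominally spans
(fs / 2^(l+1), fs / 2^l) Hz; traces are analyzed at 512 Hz, where levels
7-8 cover 1-4 Hz and levels 4-5 cover 10-40 Hz.  A band maps to every
level with at least half of its nominal span inside the requested range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt

from .core import IctalLabelSet, SignalTrace

__all__ = [
    "WaveletConfig",
    "BaselineModel",
    "band_to_levels",
    "mra_levels",
    "mra_component",
    "fit_baseline",
    "detect_ictal",
    "compute_pictal",
    "ictal_amplitude",
]


@dataclass
class WaveletConfig:
    wavelet: str = "db4"
    analysis_fs: float = 512.0
    baseline_band: tuple[float, float] = (1.0, 4.0)
    ictal_band: tuple[float, float] = (10.0, 40.0)
    k: float = 5.0
    cluster_gap: float = 2.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("k must be positive")
        for lo, hi in (self.baseline_band, self.ictal_band):
            if not 0 < lo < hi <= self.analysis_fs / 2:
                raise ValueError("bands must lie within (0, analysis_fs/2)")


@dataclass
class BaselineModel:
    mu_b: float
    sigma_b: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be non-negative")


def band_to_levels(fs: float, f_lo: float, f_hi: float,
                   max_level: int = 14) -> set[int]:
    """Detail levels whose nominal band overlaps [f_lo, f_hi] by >= 50%.

    Falls back to the single maximum-overlap level so the mapping is never
    empty.
    """
    if not 0 < f_lo < f_hi <= fs / 2:
        raise ValueError("band must satisfy 0 < f_lo < f_hi <= fs/2")
    levels: set[int] = set()
    best_level, best_frac = 1, -1.0
    for lev in range(1, max_level + 1):
        lo, hi = fs / 2 ** (lev + 1), fs / 2 ** lev
        overlap = max(0.0, min(hi, f_hi) - max(lo, f_lo))
        frac = overlap / (hi - lo)
        if frac > best_frac:
            best_level, best_frac = lev, frac
        if frac >= 0.5:
            levels.add(lev)
    return levels or {best_level}


def mra_levels(trace: SignalTrace, cfg: WaveletConfig,
               level: int) -> list[np.ndarray]:
    """Per-level MRA details [D1..Dlevel] plus final approximation.

    Uses the stationary (undecimated) transform so every component is
    time-aligned with the input sample-for-sample and, for stationary
    input, has stationary per-sample statistics — the decimated transform
    would leave a dyadic-phase-dependent variance that breaks the Gaussian
    baseline model of the detector.  The components sum to the input
    exactly (perfect reconstruction).  The input is symmetric-padded to a
    multiple of 2**level and the components truncated back.
    """
    wav = pywt.Wavelet(cfg.wavelet)
    if trace.samples.size < wav.dec_len:
        raise ValueError("trace shorter than the wavelet filter support")
    n = trace.samples.size
    pad = (-n) % (2 ** level)
    x = np.pad(trace.samples, (0, pad), mode="symmetric") if pad \
        else trace.samples
    comps = pywt.mra(x, wav, level=level, transform="swt")
    # pywt.mra orders [A_level, D_level, ..., D1]; re-order to [D1..Dlevel, A]
    approx, details = comps[0][:n], [c[:n] for c in comps[1:]]
    return [details[level - l] for l in range(1, level + 1)] + [approx]


def mra_component(trace: SignalTrace, cfg: WaveletConfig,
                  band: str | tuple[float, float] = "ictal") -> SignalTrace:
    """Sum of MRA detail components covering the requested frequency band."""
    if band == "ictal":
        f_lo, f_hi = cfg.ictal_band
    elif band == "baseline":
        f_lo, f_hi = cfg.baseline_band
    else:
        f_lo, f_hi = band
    levels = band_to_levels(trace.fs, f_lo, f_hi)
    comps = mra_levels(trace, cfg, level=max(levels))
    out = np.zeros_like(trace.samples)
    for lev in levels:
        out += comps[lev - 1]
    return replace(trace, samples=out)


def fit_baseline(component: SignalTrace,
                 window: tuple[float, float]) -> BaselineModel:
    """Gaussian baseline moments of a wavelet component in an event-free
    window (>= 10 s)."""
    a, b = window
    if not (component.t0 <= a < b <= component.t0 + component.duration + 1e-9):
        raise ValueError("baseline window outside the trace")
    if b - a < 10.0:
        raise ValueError("baseline window must span at least 10 s")
    i0 = int(round((a - component.t0) * component.fs))
    i1 = int(round((b - component.t0) * component.fs))
    seg = component.samples[i0:i1]
    return BaselineModel(mu_b=float(seg.mean()), sigma_b=float(seg.std()),
                         window=(float(a), float(b)))


def detect_ictal(component: SignalTrace, base: BaselineModel,
                 cfg: WaveletConfig, mode: str = "ctrl") -> IctalLabelSet:
    """Two-sided hard threshold at mu_b +/- k*sigma_b, then clustering.

    Suprathreshold samples separated by less than ``cluster_gap`` seconds
    belong to one event; the event spans first to last crossing.  Events
    are kept regardless of duration.
    """
    if base.sigma_b <= 0:
        raise ValueError("sigma_b must be positive")
    x = component.samples
    dev = np.abs(x - base.mu_b)
    idx = np.flatnonzero(dev > cfg.k * base.sigma_b)
    windows: list[tuple[float, float]] = []
    if idx.size:
        gap = max(1, int(round(cfg.cluster_gap * component.fs)))
        splits = np.flatnonzero(np.diff(idx) >= gap) + 1
        for cluster in np.split(idx, splits):
            onset = component.t0 + cluster[0] / component.fs
            offset = component.t0 + (cluster[-1] + 1) / component.fs
            windows.append((onset, offset))
    return IctalLabelSet(windows=windows, t_tot=component.duration, mode=mode)


def compute_pictal(labels: IctalLabelSet,
                   t_tot: float | None = None) -> float:
    """Percentage of observation time spent in the ictal state.

    P_ictal = 100 * sum_i D(i) / t_TOT.  In "stim" mode t_TOT is the
    protocol duration (``labels.t_tot`` unless overridden); in "ctrl" mode
    it is the span from the first onset to the last offset, which is
    undefined without labels.
    """
    if labels.mode == "stim":
        total = float(t_tot) if t_tot is not None else labels.t_tot
        if not labels.windows:
            return 0.0
    else:
        if not labels.windows:
            raise ValueError("t_TOT undefined: ctrl mode with no labels")
        total = labels.windows[-1][1] - labels.windows[0][0]
    return 100.0 * labels.total_duration() / total


def ictal_amplitude(traces: list[SignalTrace] | dict[str, SignalTrace],
                    labels: IctalLabelSet) -> float:
    """Maximum peak-to-peak amplitude (uV) over channels and labelled events.

    The channel subset must be kept constant across compared phases; this
    function simply reduces over whatever subset it is given.
    """
    if isinstance(traces, dict):
        traces = list(traces.values())
    if not labels.windows:
        raise ValueError("no labelled events")
    best = 0.0
    for tr in traces:
        for onset, offset in labels.windows:
            i0 = max(0, int(round((onset - tr.t0) * tr.fs)))
            i1 = min(tr.samples.size, int(round((offset - tr.t0) * tr.fs)))
            if i1 > i0:
                seg = tr.samples[i0:i1]
                best = max(best, float(seg.max() - seg.min()))
    return best
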