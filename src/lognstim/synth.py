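"""Ground-truthed surrogate MEA recordings.

Generates the three epileptiform patterns seen in 4AP-treated
hippocampus-cortex slices — the fast CA3-driven interictal pattern with
lognormal inter-event intervals, slow cortical interictal discharges, and
tonic-clonic-like ictal bursts with 10-40 Hz content — rendered onto a CA3
and a CTX channel with a fixed propagation delay and additive Gaussian
noise.  Every generated trace comes with its ground truth so detector
performance can be scored exactly.

The surrogates are statistical, not biophysical: they match only the
features the downstream detectors and distribution fits consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EventTrain, IctalLabelSet, SignalTrace, substream_seed

__all__ = [
    "SynthesisParams",
    "GroundTruth",
    "gen_interictal_times",
    "gen_ictal_windows",
    "render_trace",
    "synthesize",
]

# keep pulses that land on the duration boundary despite float rounding
_EDGE_TOL = 1e-9


@dataclass
class SynthesisParams:
    """Knobs of the surrogate recording.

    ``m``/``s`` are the log-scale mean and SD of the fast-pattern IEI, i.e.
    geometric mean exp(m) seconds and geometric SD exp(s).  Defaults follow
    the slice-experiment regime: geometric mean ~2 s, geometric SD ~1.3,
    500 uV fast transients, minutes-scale ictal recurrence with tens of
    seconds duration, 2 kHz sampling, and a 10 ms CA3->CTX delay.
    """

    m: float = float(np.log(2.0))
    s: float = float(np.log(1.3))
    duration: float = 1200.0
    fast_event_amp: float = 500.0
    fast_event_width: float = 0.05
    slow_rate: float = 2.0           # events / min
    slow_event_amp: float = 250.0
    slow_event_width: float = 0.4
    ictal_mean_interval: float = 180.0
    ictal_mean_duration: float = 40.0
    ictal_band: tuple[float, float] = (10.0, 40.0)
    ictal_amp: float = 400.0
    noise_sd: float = 20.0
    fs: float = 2000.0
    propagation_delay: float = 0.01
    fast_to_ctx: bool = True  # False emulates Schaffer-collateral disruption
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("s must be non-negative")
        for name in ("duration", "fast_event_amp", "fast_event_width",
                     "ictal_mean_interval", "ictal_mean_duration",
                     "ictal_amp", "noise_sd", "fs"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    fast_events: EventTrain
    slow_events: EventTrain
    ictal: IctalLabelSet


def gen_interictal_times(m: float, s: float, duration: float,
                         seed: int) -> EventTrain:
    """Renewal train whose intervals satisfy ln(IEI) ~ Normal(m, s).

    The first event falls at the first drawn interval; events past
    ``duration`` are discarded (a boundary event is kept).  ``s = 0``
    degenerates to a periodic train with period exp(m).  The same seed
    always reproduces the same train.
    """
    if s < 0:
        raise ValueError("s must be non-negative")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if duration == 0:
        return EventTrain(times=np.empty(0), source="synthetic")
    rng = np.random.default_rng(seed)
    mean_iei = np.exp(m + s * s / 2.0)
    chunk = max(16, int(duration / mean_iei * 1.2) + 16)
    times = np.empty(0)
    last = 0.0
    while last <= duration:
        iei = np.exp(rng.normal(m, s, chunk))
        new = last + np.cumsum(iei)
        times = np.concatenate([times, new])
        last = new[-1]
    times = times[times <= duration + _EDGE_TOL]
    return EventTrain(times=times, source="synthetic")


def gen_ictal_windows(mean_interval: float, mean_duration: float,
                      total: float, seed: int) -> IctalLabelSet:
    """Non-overlapping ictal windows from a shifted-exponential renewal model.

    Durations and inter-event gaps are shifted exponentials (shift = half
    the mean, exponential tail carrying the other half), the simplest
    renewal model with the stated means that avoids both zero-length
    events and immediate recurrences.  The onset-to-onset interval is the
    previous duration plus a gap of mean ``mean_interval -
    mean_duration``, so the realized duty cycle converges to
    ``mean_duration / mean_interval`` as ``total`` grows.
    """
    if not mean_interval > mean_duration:
        raise ValueError("mean_interval must exceed mean_duration")
    if total <= 0:
        raise ValueError("total must be positive")
    rng = np.random.default_rng(seed)
    mean_gap = mean_interval - mean_duration

    def shifted_exp(mean: float) -> float:
        return mean / 2 + float(rng.exponential(mean / 2))

    windows: list[tuple[float, float]] = []
    t = shifted_exp(mean_gap)
    while True:
        dur = shifted_exp(mean_duration)
        if t + dur > total:
            break
        windows.append((t, t + dur))
        t = t + dur + shifted_exp(mean_gap)
    return IctalLabelSet(windows=windows, t_tot=total, mode="ctrl")


def _biphasic_kernel(width: float, fs: float) -> np.ndarray:
    """Smooth biphasic transient: raised-cosine positive lobe followed by a
    smaller (0.6x) negative after-lobe, unit peak amplitude.  The asymmetry
    mirrors sharp field-potential transients and keeps the rectified peak
    unambiguous for the detector."""
    half = max(2, int(round(width * fs / 2)))
    lobe = 0.5 * (1 - np.cos(2 * np.pi * np.arange(half) / half))
    return np.concatenate([lobe, -0.6 * lobe])


def _add_events(out: np.ndarray, times: np.ndarray, kernel: np.ndarray,
                amp: float, fs: float, shift: float = 0.0) -> None:
    n = out.size
    k = kernel.size
    for t in times:
        # centre the kernel peak (quarter of the biphasic span) on t
        i0 = int(round((t + shift) * fs)) - k // 4
        a, b = max(i0, 0), min(i0 + k, n)
        if a >= b:
            continue
        out[a:b] += amp * kernel[a - i0:b - i0]


def _ictal_burst(t: np.ndarray, band: tuple[float, float], amp: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Band-limited oscillatory burst with a tonic-clonic-like envelope:
    fast rise, frequency gliding from the top to the bottom of the band."""
    dur = t[-1] - t[0] if t.size > 1 else 1.0
    x = (t - t[0]) / max(dur, 1e-9)
    f_hi, f_lo = band[1], band[0]
    freq = f_hi + (f_lo - f_hi) * x          # tonic (fast) -> clonic (slow)
    phase = 2 * np.pi * np.cumsum(freq) * (t[1] - t[0] if t.size > 1 else 0)
    ramp = min(0.5, 0.1 * dur)               # fast onset/offset (s)
    elapsed = t - t[0]
    env = np.clip(elapsed / ramp, 0, 1) * np.clip((dur - elapsed) / ramp, 0, 1)
    return amp * env * np.sin(phase + rng.uniform(0, 2 * np.pi))


def render_trace(params: SynthesisParams,
                 truth: GroundTruth) -> dict[str, SignalTrace]:
    """Render ground truth into CA3 and CTX field-potential traces.

    CA3 carries the fast interictal transients; CTX carries the same
    transients delayed by the propagation delay, plus slow interictal
    bumps and the ictal bursts.  Gaussian noise (``noise_sd``) is added to
    both channels.  Ground-truth timestamps are never altered.
    """
    fs = params.fs
    n = int(round(params.duration * fs))
    rng = np.random.default_rng(substream_seed(params.seed, "render"))
    t = np.arange(n) / fs

    ca3 = rng.normal(0.0, params.noise_sd, n)
    ctx = rng.normal(0.0, params.noise_sd, n)

    fast_k = _biphasic_kernel(params.fast_event_width, fs)
    _add_events(ca3, truth.fast_events.times, fast_k, params.fast_event_amp, fs)
    if params.fast_to_ctx:  # intact loop: CA3 events propagate to the CTX
        _add_events(ctx, truth.fast_events.times, fast_k,
                    params.fast_event_amp, fs,
                    shift=params.propagation_delay)

    slow_k = _biphasic_kernel(params.slow_event_width, fs)
    _add_events(ctx, truth.slow_events.times, slow_k, params.slow_event_amp, fs)

    for onset, offset in truth.ictal.windows:
        a, b = int(round(onset * fs)), min(int(round(offset * fs)), n)
        if b > a + 1:
            ctx[a:b] += _ictal_burst(t[a:b], params.ictal_band,
                                     params.ictal_amp, rng)

    return {
        "CA3": SignalTrace(samples=ca3, fs=fs, channel_id="CA3", region="CA3"),
        "CTX": SignalTrace(samples=ctx, fs=fs, channel_id="CTX", region="CTX"),
    }


def synthesize(params: SynthesisParams) -> tuple[dict[str, SignalTrace], GroundTruth]:
    """Draw ground truth from the parameters and render it.

    One master seed governs the whole synthesis; each component draws from
    its own named sub-stream so regenerating one component leaves the
    others unchanged.
    """
    fast = gen_interictal_times(params.m, params.s, params.duration,
                                substream_seed(params.seed, "fast"))
    slow_rng = np.random.default_rng(substream_seed(params.seed, "slow"))
    n_slow = slow_rng.poisson(params.slow_rate / 60.0 * params.duration)
    slow_times = np.sort(slow_rng.uniform(0, params.duration, n_slow))
    if slow_times.size:
        slow_times = slow_times[np.insert(np.diff(slow_times) > 1e-6, 0, True)]
    slow = EventTrain(times=slow_times, source="synthetic")
    ictal = gen_ictal_windows(params.ictal_mean_interval,
                              params.ictal_mean_duration, params.duration,
                              substream_seed(params.seed, "ictal"))
    truth = GroundTruth(fast_events=fast, slow_events=slow, ictal=ictal)
    return render_trace(params, truth), truth
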