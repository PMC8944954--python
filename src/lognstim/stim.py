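"""Surrogate stimulus-train design and ASCII export.

Three protocols: (i) the lognormal surrogate, a seeded pulse train whose
inter-pulse intervals reproduce the fitted (mu_geom, sigma_geom) of a
slice's interictal pattern; (ii) the matched periodic protocol, same
mu_geom with sigma = 0 (constant inter-pulse interval); (iii) fixed 1 Hz
pacing as the positive control.  Pulses are square biphasic
charge-balanced currents (default 100 us/phase, positive phase first);
the pulse shape is carried as metadata, not electrically simulated.

The first pulse of any train falls at the first drawn interval (not at
t = 0), so a 20-min 1 Hz train delivers exactly 1200 pulses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import substream_seed
from .lognorm import LognormalFit
from .synth import gen_interictal_times

__all__ = [
    "PulseTrain",
    "gen_lognormal_train",
    "gen_periodic_train",
    "matched_periodic",
    "sparseness_sweep",
    "export_ascii",
    "import_ascii",
]

_EDGE_TOL = 1e-9


@dataclass
class PulseTrain:
    times: np.ndarray
    duration: float
    kind: str = "custom"  # lognormal | matched_periodic | fixed_1hz | custom
    seed: int | None = None
    amplitude: float = 250.0      # uA per phase
    phase_width: float = 1e-4     # s
    polarity: str = "positive_first"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("pulse times must be strictly increasing")
        if self.times.size and (self.times[0] <= 0
                                or self.times[-1] > self.duration + _EDGE_TOL):
            raise ValueError("pulse times must lie in (0, duration]")
        if self.kind not in ("lognormal", "matched_periodic", "fixed_1hz",
                             "custom"):
            raise ValueError(f"unknown kind {self.kind!r}")

    def __len__(self) -> int:
        return self.times.size

    def count_until(self, t: float) -> int:
        return int(np.searchsorted(self.times, t, side="right"))


def gen_lognormal_train(fit: LognormalFit, duration: float,
                        seed: int, amplitude: float = 250.0) -> PulseTrain:
    """Seeded surrogate train with ln(inter-pulse interval) ~ N(m, s)."""
    if duration < 0:
        raise ValueError("duration must be non-negative")
    events = gen_interictal_times(fit.m, fit.s, duration, seed)
    return PulseTrain(times=events.times, duration=duration, kind="lognormal",
                      seed=seed, amplitude=amplitude)


def gen_periodic_train(period: float, duration: float,
                       kind: str = "fixed_1hz",
                       amplitude: float = 250.0) -> PulseTrain:
    """Pulses at period, 2*period, ..., floor(duration/period)*period."""
    if not period > 0:
        raise ValueError("period must be positive")
    if not period <= duration:
        raise ValueError("period must not exceed duration")
    count = int(np.floor(duration / period + _EDGE_TOL))
    times = period * np.arange(1, count + 1)
    return PulseTrain(times=times, duration=duration, kind=kind,
                      amplitude=amplitude)


def matched_periodic(fit: LognormalFit, duration: float,
                     amplitude: float = 250.0) -> PulseTrain:
    """Periodic protocol sharing mu_geom with the surrogate and sigma = 0."""
    return gen_periodic_train(fit.mu_geom, duration, kind="matched_periodic",
                              amplitude=amplitude)


def sparseness_sweep(mu_geom: float, sigma_fracs: list[float], trials: int,
                     duration: float, seed: int) -> pd.DataFrame:
    """Pulse counts across increasing interval variability.

    For each fraction f the log-scale SD is s = f * ln(mu_geom); each of
    the ``trials`` trials draws a fresh sub-seed that is kept constant
    across the different sigma values (so trial j is comparable between
    fractions).  Returns one row per (fraction, trial) with the count and
    the per-trial mean frequency count/duration.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if any(f < 0 for f in sigma_fracs):
        raise ValueError("sigma fractions must be non-negative")
    if mu_geom <= 1 and any(f > 0 for f in sigma_fracs):
        raise ValueError("mu_geom <= 1: ln(mu_geom) cannot scale an SD")
    m = float(np.log(mu_geom))
    trial_seeds = [substream_seed(seed, "sparseness", j) for j in range(trials)]
    rows = []
    for frac in sigma_fracs:
        s = frac * m
        for j, sj in enumerate(trial_seeds):
            train = gen_interictal_times(m, s, duration, sj)
            rows.append({
                "sigma_frac": frac,
                "trial": j,
                "count": len(train),
                "mean_freq": len(train) / duration,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ASCII dialect: header comments then two columns "time_ms value_uA";
# each pulse expands to (+A for one phase width, -A for one phase width, 0).


def export_ascii(train: PulseTrain, path: str | Path) -> None:
    """Write a train in the two-column ASCII stimulus dialect.

    Times are printed in ms with 1 us resolution; each pulse is a
    charge-balanced biphasic step (+A, -A, return to 0).
    """
    lines = [
        f"# kind: {train.kind}",
        f"# seed: {'' if train.seed is None else train.seed}",
        f"# duration_s: {train.duration:.6f}",
        f"# amplitude_uA: {train.amplitude:.6f}",
        f"# phase_width_us: {train.phase_width * 1e6:.3f}",
        "time_ms\tvalue_uA",
    ]
    a = train.amplitude if train.polarity == "positive_first" else -train.amplitude
    pw_ms = train.phase_width * 1e3
    for t in train.times:
        t_ms = t * 1e3
        lines.append(f"{t_ms:.3f}\t{a:+.3f}")
        lines.append(f"{t_ms + pw_ms:.3f}\t{-a:+.3f}")
        lines.append(f"{t_ms + 2 * pw_ms:.3f}\t{0.0:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def import_ascii(path: str | Path) -> PulseTrain:
    """Round-trip reader for the ASCII dialect (1 us time resolution)."""
    header: dict[str, str] = {}
    times = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
        elif not line[0].isalpha():
            t_ms, val = line.split()
            if abs(float(val)) > 0:  # phase onset rows only
                times.append(round(float(t_ms), 3))
    # first row of each biphasic pair is the pulse time
    pulse_times = np.array(times[::2]) / 1e3 if times else np.empty(0)
    seed = header.get("seed", "")
    return PulseTrain(
        times=pulse_times,
        duration=float(header.get("duration_s", pulse_times[-1] if times else 0.0)),
        kind=header.get("kind", "custom"),
        seed=int(seed) if seed else None,
        amplitude=float(header.get("amplitude_uA", 250.0)),
        phase_width=float(header.get("phase_width_us", 100.0)) / 1e6,
    )
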