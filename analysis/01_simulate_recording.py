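"""Generate the reference synthetic MEA recording used by the later stages.

A 20-min two-channel (CA3 + CTX) recording at 2 kHz: fast CA3-driven
interictal events with lognormal IEIs (geometric mean 2 s, geometric SD
1.3), slow cortical discharges, and minutes-scale ictal bursts on the CTX
channel.  Writes the signal (CSV + JSON sidecar) and the ground truth to
scratch/recording/ (the raw trace is bulky; only derived tables live under
results/).  Run this before 02 and 03.
"""

from pathlib import Path

from lognstim import core, synth

OUT = Path(__file__).resolve().parent.parent / "scratch" / "recording"
SEED = 2022


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    # disconnected-slice scenario: the CA3 output to the CTX is severed, so
    # the CTX shows slow discharges and ictal activity while the fast
    # pattern stays confined to the CA3
    params = synth.SynthesisParams(duration=1200.0, seed=SEED,
                                   ictal_mean_duration=30.0,
                                   fast_to_ctx=False)
    traces, truth = synth.synthesize(params)
    core.write_signal(traces, OUT / "signal.csv", OUT / "signal.json")
    core.write_events(truth.fast_events, OUT / "truth_fast_events.json")
    core.write_labels(truth.ictal, OUT / "truth_ictal.json")
    print(f"wrote {params.duration:.0f} s recording to {OUT}")
    print(f"  fast interictal events: {len(truth.fast_events)}")
    print(f"  slow events:            {len(truth.slow_events)}")
    print(f"  ictal windows:          {len(truth.ictal)} "
          f"({truth.ictal.total_duration():.0f} s total)")


if __name__ == "__main__":
    main()
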