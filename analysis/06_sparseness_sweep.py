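"""Pulse sparseness as a function of inter-pulse interval variability.

Generates 10 trials of 60-s pulse trains at geometric mean 2 s with
log-scale SD sigma in {0, 0.5 mu, mu} (mu = ln 2), sharing trial seeds
across sigma values, and summarizes counts and mean frequencies.
Writes results/sparseness_sweep.csv.
"""

from pathlib import Path

from lognstim import stim

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 2022


def main() -> None:
    table = stim.sparseness_sweep(2.0, [0.0, 0.5, 1.0], trials=10,
                                  duration=60.0, seed=SEED)
    table.to_csv(ROOT / "sparseness_sweep.csv", index=False)
    summary = table.groupby("sigma_frac").agg(
        mean_count=("count", "mean"), sd_count=("count", "std"),
        mean_freq=("mean_freq", "mean"))
    print(summary.to_string())
    print("\npulse sparseness grows with sigma: mean frequency drops from "
          f"{summary['mean_freq'][0.0]:.2f} Hz (periodic) to "
          f"{summary['mean_freq'][1.0]:.2f} Hz at sigma = mu")


if __name__ == "__main__":
    main()
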