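"""Compute looking-at-nothing metrics per participant.

Labels fixations by AOI, then derives LAN duration, LAN strength (toward the
most-similar exemplar under each participant's median fitted cue weights),
within-trial time bins, trial-level location counts, and split-half
reliability.  Reads results/data/ and results/fits.csv, writes
results/gaze.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from rulexgaze.environment import Environment
from rulexgaze.gaze import participant_gaze_summary

ROOT = Path(__file__).resolve().parents[1]


def normalized_weights(fits: pd.DataFrame) -> dict:
    out = {}
    for r in fits.itertuples(index=False):
        a1, a2 = abs(r.beta1_median), abs(r.beta2_median)
        out[int(r.participant)] = (
            (a1 / (a1 + a2), a2 / (a1 + a2)) if a1 + a2 > 0 else (0.5, 0.5)
        )
    return out


def main() -> None:
    env = Environment.multiplicative()
    data = ROOT / "results" / "data"
    fixations = pd.read_csv(data / "fixations.csv")
    trials = pd.read_csv(data / "trials.csv")
    fits = pd.read_csv(ROOT / "results" / "fits.csv")
    gaze = participant_gaze_summary(
        fixations, trials, env, weights=normalized_weights(fits)
    )
    gaze.to_csv(ROOT / "results" / "gaze.csv", index=False)
    print(f"gaze metrics for {len(gaze)} participants")
    print(f"  trials with any exemplar gaze: {gaze['prop_lan_trials'].mean():.1%}")
    print(f"  mean LAN duration: {gaze['lan_duration'].mean():.3f}")
    print(f"  mean LAN strength: {gaze['lan_strength'].mean():.3f}")
    bins = gaze[[f"bin{i}" for i in range(1, 6)]].mean()
    print("  LAN by time bin:", ", ".join(f"{v:.3f}" for v in bins))
    print(f"  split-half reliability (mean r): {gaze['split_half_r'].mean():.3f}")
    print("wrote results/gaze.csv")


if __name__ == "__main__":
    argparse.ArgumentParser().parse_args()
    main()
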