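"""Simulate the default synthetic cohort.

Generates 48 participants' worth of test-phase judgments (16 stimuli x 8
blocks), matched fixation sequences with alpha-coupled looking-at-nothing,
and the generating-parameter truth table.  Writes CSVs under results/data/.
"""

import argparse
from pathlib import Path

from rulexgaze.environment import Environment
from rulexgaze.simulate import CohortSpec, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    env = Environment.multiplicative()
    spec = CohortSpec(n_participants=48, seed=seed)
    data = simulate_cohort(spec, env)
    outdir = ROOT / "results" / "data"
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in data.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    truth = data["truth"]
    print(f"cohort: {spec.n_participants} participants, seed {seed}")
    print(f"judgments: {len(data['judgments'])} trials "
          f"({len(data['judgments']) // spec.n_participants} per participant)")
    print(f"fixations: {len(data['fixations'])} events across "
          f"{len(data['trials'])} trials")
    print(f"generating alpha: mean {truth['alpha'].mean():.3f}, "
          f"range [{truth['alpha'].min():.3f}, {truth['alpha'].max():.3f}]")
    print(f"wrote judgments/fixations/trials/truth to {outdir}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
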