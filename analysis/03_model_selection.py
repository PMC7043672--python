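"""Run the hierarchical model-selection ladder on the synthetic dataset.

Stages mirror the competition order of the study design: prey phenotype
count, plastic-resistance conversion mechanism, signal source,
phage-resistance origin, attack saturation, mortality mode.  Run sizes
are reduced (default 100 particles x 4 generations x 3 runs per stage)
so the whole ladder finishes in tens of minutes on one CPU; pass
--particles/--generations/--runs to scale up.

Writes results/stage_results.csv.
"""

import argparse
from pathlib import Path

from dualpred.abc import SMCConfig
from dualpred.io import read_dataset
from dualpred.pipeline import default_stage_plan, run_plan

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--particles", type=int, default=100)
    ap.add_argument("--generations", type=int, default=4)
    ap.add_argument("--runs", type=int, default=3)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    obs = read_dataset(OUT / "dataset")
    cfg = SMCConfig(n_particles=args.particles,
                    max_generations=args.generations, seed=args.seed)
    table = run_plan(default_stage_plan(), obs, cfg, n_runs=args.runs)
    table.to_csv(OUT / "stage_results.csv", index=False)
    print(table.to_string(index=False))
    winners = table[table["winner"]].groupby("stage")["candidate"].first()
    print("\nstage winners:")
    print(winners.to_string())


if __name__ == "__main__":
    main()
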