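"""Two-stage grid search for the cardinal temperatures.

Reads the synthetic bundle (step 01), splits both observation streams
80/20 (blocked), evaluates the five objectives per candidate triplet and
writes the audit trail and the winning triplet to results/.

The default grid is a reduced neighbourhood of plausible cool-climate
values (1 °C coarse steps, 0.3 °C refinement): a deliberate problem-size
choice that keeps a full two-stage sweep at a few hundred mixed-model
refits.  --full-grid switches to the complete search space (t_base from
-60 °C upward), which multiplies the sweep by ~100.
"""

import argparse
import json
import pathlib

import pandas as pd

from vinedev.cardinal_optimization import (
    GridSpec,
    OptimizationConfig,
    WeatherCache,
    coarse_grid_paper,
    run_two_stage,
)
from vinedev.pipeline import apex_split, phenology_split


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/synthetic")
    ap.add_argument("--out", default="results")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--full-grid", action="store_true")
    ap.add_argument("--refine-step", type=float, default=0.3)
    args = ap.parse_args()

    data = pathlib.Path(args.data)
    ratings = pd.read_csv(data / "ratings.csv")
    apex = pd.read_csv(data / "apex.csv")
    weather = {}
    for f in sorted(data.glob("weather_*.csv")):
        year = int(f.stem.split("_")[1])
        weather[year] = pd.read_csv(f)

    ptr, pte, _ = phenology_split(ratings, 0.8, seed=args.seed)
    atr, ate, _ = apex_split(apex, 0.8, seed=args.seed + 1)
    print(f"splits: phenology {len(ptr)}/{len(pte)}, apex {len(atr)}/{len(ate)}")

    coarse = coarse_grid_paper() if args.full_grid else GridSpec(
        tuple(range(8, 14)), tuple(range(16, 23)), tuple(range(22, 29)))
    cfg = OptimizationConfig(coarse=coarse, refine_step=args.refine_step)
    res = run_two_stage(ptr, pte, atr, ate, WeatherCache(weather), cfg, progress=True)

    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    res.audit.to_csv(out / "cardinal_audit.csv", index=False)
    winner = {"coarse": res.coarse_winner.as_tuple(), "final": res.winner.as_tuple(),
              "coarse_votes": res.coarse_counts[res.coarse_winner],
              "final_votes": res.final_counts[res.winner]}
    (out / "cardinal_winner.json").write_text(json.dumps(winner, indent=2))
    print(f"coarse winner {winner['coarse']} ({winner['coarse_votes']} votes)")
    print(f"final  winner {winner['final']} ({winner['final_votes']} votes)")
    print(f"audit: {len(res.audit)} triplets, {int(res.audit.feasible.sum())} feasible")


if __name__ == "__main__":
    main()
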