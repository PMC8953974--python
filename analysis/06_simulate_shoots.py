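"""Stochastic shoot-population simulation from the fitted posteriors.

Loads the phenology, apex and internode posteriors (steps 03-05), predicts
budburst dates for one year, simulates 80 shoots per retained date and
writes per-day population summaries plus the per-shoot trajectories.
"""

import argparse
import json
import pathlib

import pandas as pd

from vinedev.apex_appearance import IARDistribution
from vinedev.inference_core import PosteriorSamples
from vinedev.internode_growth import GrowthPosterior
from vinedev.phenology import PhenologyPosterior
from vinedev.shoot_simulation import (
    SimulationConfig,
    length_class_frequencies,
    population_summary,
    simulate_budburst_dates,
    simulate_population,
)
from vinedev.thermal_time import CardinalTemperatures, build_calendar


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/synthetic")
    ap.add_argument("--results", default="results")
    ap.add_argument("--year", type=int, default=2018)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cardinal", type=float, nargs=3, default=(10.8, 19.0, 24.7))
    ap.add_argument("--shoots-per-date", type=int, default=80)
    args = ap.parse_args()

    res = pathlib.Path(args.results)
    weather = pd.read_csv(pathlib.Path(args.data) / f"weather_{args.year}.csv")
    cal = build_calendar(weather, CardinalTemperatures(*args.cardinal))

    phen = PhenologyPosterior(
        variant="final-exgaussian", likelihood="exgaussian",
        draws=PosteriorSamples.from_csv(res / "phenology_posterior.csv"),
        trt_levels=("aCO2", "eCO2"), year_levels=(2018, 2019))
    iar_spec = json.loads((res / "iar.json").read_text())
    iar = IARDistribution(mu=iar_spec["mu"], sigma=iar_spec["sigma"])
    growth = GrowthPosterior(
        variant="final",
        draws=PosteriorSamples.from_csv(res / "internode_posterior.csv"),
        shoot_labels=[], level_names=[""])

    cfg = SimulationConfig(seed=args.seed, shoots_per_date=args.shoots_per_date)
    dates = simulate_budburst_dates(phen, cal, cfg)
    print(f"{args.year}: {len(dates.retained)} retained budburst dates "
          f"(doy {dates.retained[0][0]}..{dates.retained[-1][0]})")
    pop = simulate_population(dates, cal, iar, growth, cfg)
    print(f"simulated {len(pop.trajectories)} shoots")

    summary = population_summary(pop)
    summary.to_csv(res / f"shoot_population_{args.year}.csv", index=False)
    traj = pd.concat([t.to_frame() for t in pop.trajectories], ignore_index=True)
    traj.to_csv(res / f"shoot_trajectories_{args.year}.csv", index=False)
    classes = length_class_frequencies(pop)
    print("normalized-length classes:", classes.round(3).to_dict())
    last = summary.iloc[-1]
    print(f"day {int(last['doy'])}: weighted mean shoot length "
          f"{last['weighted_mean']:.1f} cm (q25-q75 {last['q25']:.1f}-{last['q75']:.1f})")


if __name__ == "__main__":
    main()
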