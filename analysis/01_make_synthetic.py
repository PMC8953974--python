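"""Generate the synthetic VineyardFACE-style dataset used by all later steps.

Writes weather, phenology ratings, apex digitizations and internode lengths
(plus the ground-truth sidecar) to results/synthetic/.
"""

import argparse
import pathlib

from vinedev.synthetic_data import GroundTruth, make_bundle


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/synthetic")
    args = ap.parse_args()

    bundle = make_bundle(GroundTruth(), seed=args.seed)
    out = pathlib.Path(args.out)
    bundle.write(out)
    print(f"wrote synthetic bundle to {out}/")
    print(f"  ratings:    {len(bundle.ratings):5d} rows")
    print(f"  apex:       {len(bundle.apex):5d} rows")
    print(f"  internodes: {len(bundle.internodes):5d} rows")
    for year, cal in bundle.calendars.items():
        print(f"  {year}: CDD reaches {cal.cdd[-1]:.1f} by doy {cal.doy[-1]}")


if __name__ == "__main__":
    main()
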