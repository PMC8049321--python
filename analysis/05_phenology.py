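#!/usr/bin/env python
"""Compute percentile-based migration timing and its interannual trends.

Arrival / peak / departure are the days on which cumulative annual
sightings reach 10/50/90% of the annual total; trends on year are
labelled L/Q/C with the sign of the top coefficient.
"""

import argparse
import json

import pandas as pd

from whaletrends.cli import run_stage


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/pipeline")
    args = ap.parse_args()

    run_stage("phenology", args.outdir, seed=args.seed)
    timing = pd.read_csv(f"{args.outdir}/timing.csv")
    trends = json.load(open(f"{args.outdir}/timing_trends.json"))
    for sp, metrics in trends.items():
        ok = timing[(timing["species"] == sp) & (~timing["excluded"])]
        arr = metrics["arrival_day"]
        slope = arr["params"].get("year")
        slope_s = f" ({slope:+.1f} d/yr)" if arr["order"] == 1 and slope is not None else ""
        print(
            f"{sp:12s} mean arrival day {ok['arrival_day'].mean():5.1f}, "
            f"residency {ok['residency_days'].mean():5.1f} d; "
            f"arrival trend {arr['shape']}{slope_s}, departure {metrics['departure_day']['shape']}"
        )


if __name__ == "__main__":
    main()
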