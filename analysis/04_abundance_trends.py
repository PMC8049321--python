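#!/usr/bin/env python
"""Fit negative-binomial weekly sighting-trend models per species.

Aggregates filtered daily counts to weeks with a log-effort offset and
selects the year-trend shape (linear/quadratic/cubic) by the significance
of the highest-order year term.  Prints the chosen shape and dispersion
per species dataset.
"""

import argparse
import json
import warnings

from whaletrends.cli import run_stage


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/pipeline")
    args = ap.parse_args()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        run_stage("trends", args.outdir, seed=args.seed)
    fits = json.load(open(f"{args.outdir}/trend_fits.json"))
    for sp, fit in fits.items():
        alpha = fit.get("alpha")
        alpha_s = f", dispersion alpha={alpha:.2f}" if alpha else ""
        print(f"{sp:12s} year-trend shape {fit['shape']}{alpha_s}, AIC {fit['aic']:.0f}")


if __name__ == "__main__":
    main()
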