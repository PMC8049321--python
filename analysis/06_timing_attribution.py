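#!/usr/bin/env python
"""Attribute timing variation to environmental drivers and validate forecasts.

Univariate screening feeds a hierarchy-preserving backward elimination
(P<0.05, VIF<10); the retained model is refit with pre-season covariates
only (forecast variant) and validated by year-removal.  Prints retained
terms and the full / forecast / validation R-squareds per model.
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
        run_stage("timing", args.outdir, seed=args.seed)
    models = json.load(open(f"{args.outdir}/timing_models.json"))
    val = json.load(open(f"{args.outdir}/forecast_validation.json"))
    for sp, metrics in models.items():
        for metric, m in metrics.items():
            v = val[sp][metric]
            if not m["significant"]:
                print(f"{sp} {metric}: not significant")
                continue
            terms = ", ".join(f"{k} {lab}" for k, lab in m["terms"].items())
            ratio = v["ratio_forecast_to_full"]
            ratio_s = f"{ratio:.3f}" if ratio == ratio else "n/a"
            print(
                f"{sp} {metric}: R2={v['full_r2']:.3f} "
                f"forecast/full={ratio_s} validation R2={v['validation_r2']:.3f} | {terms}"
            )


if __name__ == "__main__":
    main()
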