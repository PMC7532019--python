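#!/usr/bin/env python
"""Stage 4 — rank the four flow-vs-speed model variants.

Scores the hydrostatic-only, centrifugal-only and combined predictions
(parameter-free, geometry-derived) and the fitted pinned model against the
stage-2 campaign by weighted SSR.  On data generated with capillary pinning
the pinned model should win by orders of magnitude, mirroring the visual
model comparison of measured versus calculated flow curves.  Writes
results/model_comparison.csv.
"""

import argparse
from pathlib import Path

import discflow as df
from discflow.burst_fit import FlowMeasurementSet, compare_variants
from discflow.synthetic_data import CampaignDesign, simulate_campaign

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    geom = df.default_geometry()
    water = df.water_properties(37.0)
    csv = RESULTS / f"campaign_seed{args.seed}.csv"
    if csv.exists():
        campaign = FlowMeasurementSet.read_csv(csv)
    else:
        campaign = simulate_campaign(CampaignDesign(seed=args.seed), geom, water)

    table = compare_variants(campaign, geom, water)
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "model_comparison.csv"
    table.to_csv(out, index=False)

    print(table.to_string(index=False))
    best = table.iloc[0]
    print(f"\nbest variant: {best['variant']} "
          f"(weighted SSR {best['weighted_SSR']:.1f}, R^2 {best['r_squared']:.3f})")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
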