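#!/usr/bin/env python
"""Value avoidable-mortality reductions as a share of annual income.

Extrapolates the VSL from the anchor economy with income elasticities,
adjusts by discounted remaining life expectancy, applies the concave
valuation to each region-sex-age-cause-year gap, and aggregates to value
shares (% of annual income).  Writes results/base_run/economic_value.csv
and value_rates_of_change.csv.
"""

import argparse
from pathlib import Path

from evam.pipeline import ScenarioConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--world", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results/base_run"))
    args = ap.parse_args()

    cfg = ScenarioConfig(
        mortality=str(args.world / "mortality.csv"),
        population=str(args.world / "population.csv"),
        income=str(args.world / "income.csv"),
        income_growth=str(args.world / "income_growth.csv"),
        metadata=str(args.world / "country_metadata.csv"),
        out_dir=str(args.out),
        log_level="WARNING",
    )
    arts = run_pipeline(cfg)
    values, changes = arts["values"], arts["changes"]

    sel = values[
        (values["sex"] == "both")
        & (values["year"] == 2019)
        & (values["level"] == 2)
        & (values["cause"].isin(["cvds", "malignant_neoplasms"]))
    ]
    print("value of closing the gap, 2019 (% of annual income, both sexes):")
    print(
        sel.pivot_table(index="region", columns="cause", values="value_pct_income")
        .to_string(float_format=lambda x: f"{x:.2f}")
    )

    ch = changes[
        (changes["sex"] == "both") & (changes["cause"] == "cvds")
    ].pivot_table(index="region", columns="period", values="pct_per_year")
    print("\nannualized change of the CVD value share (%/yr):")
    print(ch.to_string(float_format=lambda x: f"{x:+.2f}"))
    print(f"\nwrote {args.out / 'economic_value.csv'} and value_rates_of_change.csv")


if __name__ == "__main__":
    main()
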