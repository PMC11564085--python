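"""Avoidable mortality: probabilities of dying and gaps to the frontier.

Rates are converted to annual probabilities of dying under a constant
hazard over a 1-year period, q = 1 - exp(-m).  The avoidable mortality of
a population is the gap between its probability of dying and the frontier
probability, clamped at zero by default (a 10th-percentile frontier means
some country cells sit below it; a negative gap is not meaningful as a
valuation input).

Country rates are population-weighted into regions first; probabilities
and gaps are then computed at region level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .causes import SEX_SPECIFIC_CAUSES

__all__ = [
    "rate_to_probability",
    "avoidable_gap",
    "aggregate_region",
    "frontier_by_sex",
    "compute_gaps",
]


def rate_to_probability(m):
    """q = 1 - exp(-m): annual probability of dying at rate ``m``."""
    m = np.asarray(m, dtype=float)
    if (m < 0).any():
        raise ValueError("death rates must be non-negative")
    q = -np.expm1(-m)
    return float(q) if q.ndim == 0 else q


def avoidable_gap(q_country, q_frontier, clamp: bool = True):
    """delta = q_country - q_frontier, clamped at 0 unless disabled."""
    q_c = np.asarray(q_country, dtype=float)
    q_f = np.asarray(q_frontier, dtype=float)
    for q in (q_c, q_f):
        if ((q < 0) | (q > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
    d = q_c - q_f
    if clamp:
        d = np.maximum(d, 0.0)
    return float(d) if d.ndim == 0 else d


def aggregate_region(
    values: pd.DataFrame,
    population: pd.DataFrame,
    region_map: pd.DataFrame | dict,
    value_col: str = "rate",
) -> pd.DataFrame:
    """Population-weighted aggregation of country values into regions.

    Weights are country populations within each region-sex-age-year cell,
    so the region value always lies between the member-country extremes.
    """
    if isinstance(region_map, dict):
        lut = region_map
    else:
        lut = dict(zip(region_map["iso3"], region_map["region"]))
    unmapped = sorted(set(values["iso3"]) - set(lut))
    if unmapped:
        raise ValueError(f"unmapped country/ies: {', '.join(unmapped)}")

    pop = population[["iso3", "sex", "age_group", "year", "pop"]]
    merged = values.merge(pop, on=["iso3", "sex", "age_group", "year"], how="left")
    if merged["pop"].isna().any():
        missing = merged.loc[merged["pop"].isna(), "iso3"].unique()
        raise ValueError(f"population missing for: {sorted(missing)}")
    merged["region"] = merged["iso3"].map(lut)

    keys = ["region", "sex", "age_group", "year"]
    extra = [c for c in values.columns if c not in keys + ["iso3", "country", value_col]]
    keys = keys + extra
    merged["_wv"] = merged[value_col] * merged["pop"]
    g = merged.groupby(keys, sort=False)
    out = (g["_wv"].sum() / g["pop"].sum()).rename(value_col).reset_index()
    return out


def frontier_by_sex(frontier: pd.DataFrame) -> pd.DataFrame:
    """Expand a mixed-sex frontier surface to explicit female/male rows."""
    both = frontier[frontier["sex"] == "both"]
    split = frontier[frontier["sex"] != "both"]
    expanded = pd.concat(
        [both.assign(sex="female"), both.assign(sex="male"), split], ignore_index=True
    )
    return expanded


def compute_gaps(
    region_rates: pd.DataFrame,
    frontier_scaled: pd.DataFrame,
    clamp: bool = True,
) -> pd.DataFrame:
    """Per region-sex-age-cause-year avoidable mortality.

    ``region_rates``: (region, sex, age_group, cause, year, rate).
    ``frontier_scaled``: mixed-sex frontier surface with ``value`` rates.
    Returns the merged table with ``q_country, q_frontier, delta``.
    """
    fr = frontier_by_sex(frontier_scaled)[["age_group", "sex", "cause", "year", "value"]]
    fr = fr.rename(columns={"value": "frontier_rate"})
    merged = region_rates.merge(fr, on=["age_group", "sex", "cause", "year"], how="left")
    if merged["frontier_rate"].isna().any():
        bad = merged[merged["frontier_rate"].isna()].iloc[0]
        raise ValueError(
            f"frontier missing for cause={bad['cause']} age={bad['age_group']} "
            f"sex={bad['sex']} year={bad['year']}"
        )
    merged["q_country"] = rate_to_probability(merged["rate"].to_numpy())
    merged["q_frontier"] = rate_to_probability(merged["frontier_rate"].to_numpy())
    merged["delta"] = avoidable_gap(
        merged["q_country"].to_numpy(), merged["q_frontier"].to_numpy(), clamp=clamp
    )
    return merged
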