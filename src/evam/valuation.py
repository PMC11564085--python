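"""Economic value of reducing avoidable mortality.

The value that a population places on a reduction delta in its annual
probability of dying from a cause is anchored to the value per
statistical life (VSL).  The VSL of a country/region is extrapolated from
an anchor economy's VSL (anchor ratio x anchor GNI per capita) with an
income elasticity (0.8 above the anchor income, 1.2 below, in the base
case) and floored at 20 times own GNI per capita.

Because avoidable mortality gaps are non-marginal, a constant-VSL
valuation would overstate the benefit; the value function

    v(delta) = y * (1 - exp(-(VSL* / y) * delta)),   y = GNI per capita

is strictly increasing and concave in delta, equals VSL* * delta in the
small-risk limit, and is bounded by annual income — the metric reads as
the share of one year's income a person would forgo to face the frontier
risk instead.  VSL* is the VSL adjusted by the ratio of discounted
remaining life expectancy at the age of death to that at the anchor age
(40), which is where the discount rate enters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .causes import CauseTree
from .synthetic import LIFE_TABLE_CAP, age_group_midpoints, age_group_widths

__all__ = [
    "ValuationParams",
    "extrapolate_vsl",
    "discounted_remaining_life",
    "value_of_reduction",
    "economic_value_share",
    "annualized_change",
    "project_income",
]


@dataclass(frozen=True)
class ValuationParams:
    """Economic parameters of the valuation.

    Base case: VSL = 160 x anchor GNI per capita at the anchor economy,
    elasticity 0.8 above / 1.2 below the anchor income, VSL/GNI floor 20,
    3%/year discounting, VSL anchored at age 40.
    """

    vsl_anchor_ratio: float = 160.0
    elasticity_above: float = 0.8
    elasticity_below: float = 1.2
    floor_ratio: float = 20.0
    discount_rate: float = 0.03
    anchor_age: float = 40.0
    life_table_cap: float = LIFE_TABLE_CAP

    def __post_init__(self):
        if self.vsl_anchor_ratio <= 0 or self.floor_ratio <= 0:
            raise ValueError("VSL ratios must be positive")
        if not (0 <= self.discount_rate < 1):
            raise ValueError("discount_rate must be in [0, 1)")
        if self.elasticity_above <= 0 or self.elasticity_below <= 0:
            raise ValueError("elasticities must be positive")

    def with_elasticity(self, eta: float) -> "ValuationParams":
        """Sensitivity variant: one elasticity on both sides of the anchor."""
        return replace(self, elasticity_above=eta, elasticity_below=eta)


def extrapolate_vsl(gni_c, gni_anchor, params: ValuationParams):
    """VSL of an economy with income ``gni_c`` given the anchor income.

    VSL = ratio * gni_anchor * (gni_c / gni_anchor)^eta, then floored at
    ``floor_ratio * gni_c``.
    """
    gni_c = np.asarray(gni_c, dtype=float)
    gni_anchor = np.asarray(gni_anchor, dtype=float)
    if (gni_c <= 0).any() or (gni_anchor <= 0).any():
        raise ValueError("incomes must be positive")
    eta = np.where(gni_c < gni_anchor, params.elasticity_below, params.elasticity_above)
    vsl = params.vsl_anchor_ratio * gni_anchor * (gni_c / gni_anchor) ** eta
    vsl = np.maximum(vsl, params.floor_ratio * gni_c)
    return float(vsl) if vsl.ndim == 0 else vsl


def _single_age_hazard(
    age_rates: pd.Series, age_groups: tuple[str, ...], cap: float
) -> np.ndarray:
    """Expand group death rates to a per-single-year hazard array 0..cap-1."""
    widths = age_group_widths(age_groups).astype(int)
    mu = np.repeat(age_rates.reindex(list(age_groups)).to_numpy(dtype=float), widths)
    return mu[: int(cap)]


def discounted_remaining_life(
    allcause_rates: pd.Series,
    from_age: float,
    discount_rate: float,
    cap: float = LIFE_TABLE_CAP,
) -> float:
    """Survival-weighted, discounted expected years of life from ``from_age``.

    ``allcause_rates`` maps age-group labels to all-cause death rates for
    one region-year-sex.  A period life table with constant hazard within
    groups is run from ``from_age`` (fractional ages allowed) to the cap:

        DRL = sum_t exp(-H(t)) * (1 + r)^(-t),  t = 0, 1, ... < cap - a0

    where H(t) is the cumulative hazard from ``from_age``.  Strictly
    decreasing in r for nondegenerate survival.
    """
    age_groups = tuple(allcause_rates.index)
    mu = _single_age_hazard(allcause_rates, age_groups, cap)
    a0 = from_age
    n_years = int(np.ceil(cap - a0))
    if n_years <= 0:
        return 0.0
    # hazard over each whole year lived from a0; a year of life spans at
    # most two integer-age cells, so split the exposure across them
    t = np.arange(n_years, dtype=float)
    lo = a0 + t
    hi = np.minimum(lo + 1.0, cap)
    i_lo = np.floor(lo).astype(int)
    mu_lo = mu[np.minimum(i_lo, len(mu) - 1)]
    mu_hi = mu[np.minimum(i_lo + 1, len(mu) - 1)]
    part1 = np.minimum(i_lo + 1.0, hi) - lo
    part2 = np.maximum((hi - lo) - part1, 0.0)
    haz = part1 * mu_lo + part2 * mu_hi
    cum = np.concatenate([[0.0], np.cumsum(haz[:-1])])
    disc = (1.0 + discount_rate) ** (-np.arange(n_years, dtype=float))
    return float(np.sum(np.exp(-cum) * disc))


def value_of_reduction(delta, income, vsl, le_ratio=1.0):
    """Per-capita value of reducing the probability of dying by ``delta``.

    v = y * (1 - exp(-(vsl * le_ratio / y) * delta)).  v(0) = 0, dv/ddelta
    at 0 equals the age-adjusted VSL, strictly increasing, strictly
    concave, bounded by income.
    """
    delta = np.asarray(delta, dtype=float)
    if ((delta < 0) | (delta > 1)).any():
        raise ValueError("delta must lie in [0, 1]")
    income = np.asarray(income, dtype=float)
    vsl_star = np.asarray(vsl, dtype=float) * np.asarray(le_ratio, dtype=float)
    v = income * -np.expm1(-(vsl_star / income) * delta)
    return float(v) if v.ndim == 0 else v


def annualized_change(v1: float, v2: float, t1: int, t2: int) -> float:
    """Percent-per-year rate of change between two value shares."""
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    if v1 == 0 or np.isnan(v1) or np.isnan(v2):
        return float("nan")
    return 100.0 * ((v2 / v1) ** (1.0 / (t2 - t1)) - 1.0)


def project_income(
    income: pd.DataFrame,
    growth_rates: pd.DataFrame,
    to_year: int,
    base_year: int = 2021,
) -> pd.DataFrame:
    """Extend a GNI-per-capita table through ``to_year``.

    Growth is applied multiplicatively from the ``base_year`` level using
    each country's listed rate; countries without a listed rate use the
    average of the listed rates (the world-average fallback).
    """
    lut = dict(zip(growth_rates["iso3"], growth_rates["growth_rate"]))
    last = income[income["year"] == base_year]
    if last.empty:
        raise ValueError(f"income table does not cover base year {base_year}")
    world_avg = float(np.mean(list(lut.values()))) if lut else 0.0
    horizon = np.arange(base_year + 1, to_year + 1)
    if len(horizon) == 0:
        return income.copy()
    rows = []
    for _, r in last.iterrows():
        g = lut.get(r["iso3"], world_avg)
        rows.append(
            pd.DataFrame(
                {
                    "iso3": r["iso3"],
                    "year": horizon,
                    "gni_pc": r["gni_pc"] * (1.0 + g) ** (horizon - base_year),
                }
            )
        )
    out = pd.concat([income[income["year"] <= base_year]] + rows, ignore_index=True)
    return out.sort_values(["iso3", "year"], ignore_index=True)


def _life_ratios(
    region_allcause: pd.DataFrame,
    params: ValuationParams,
    age_groups: tuple[str, ...],
) -> pd.DataFrame:
    """Discounted-remaining-life ratio to the anchor age for every
    (region, sex, year, age_group)."""
    mids = dict(zip(age_groups, age_group_midpoints(age_groups)))
    rows = []
    for (region, sex, year), grp in region_allcause.groupby(
        ["region", "sex", "year"], sort=False
    ):
        sched = grp.set_index("age_group")["rate"]
        anchor = discounted_remaining_life(
            sched, params.anchor_age, params.discount_rate, params.life_table_cap
        )
        for ag in age_groups:
            drl = discounted_remaining_life(
                sched, mids[ag], params.discount_rate, params.life_table_cap
            )
            rows.append((region, sex, year, ag, drl / anchor))
    return pd.DataFrame(rows, columns=["region", "sex", "year", "age_group", "le_ratio"])


def economic_value_share(
    gaps: pd.DataFrame,
    region_income: pd.DataFrame,
    region_population: pd.DataFrame,
    region_allcause: pd.DataFrame,
    anchor_income: pd.DataFrame,
    params: ValuationParams,
    tree: CauseTree,
) -> pd.DataFrame:
    """Value of closing avoidable mortality, as % of annual income.

    Inputs are region-level: ``gaps`` (region, sex, age_group, cause,
    year, delta), ``region_income`` (region, year, gni_pc),
    ``region_population`` (region, sex, age_group, year, pop),
    ``region_allcause`` (region, sex, age_group, year, rate) for the life
    tables, and ``anchor_income`` (year, gni_pc) for the VSL anchor.

    Returns (region, sex, cause, level, year, value_pct_income,
    absolute_value_pc) including population-weighted both-sex rows.
    """
    age_groups = tuple(dict.fromkeys(region_population["age_group"]))

    inc = region_income.merge(
        anchor_income.rename(columns={"gni_pc": "gni_anchor"}), on="year", how="left"
    )
    if inc["gni_anchor"].isna().any() or inc["gni_pc"].isna().any():
        raise ValueError("income missing for a region-year")
    inc["vsl"] = extrapolate_vsl(
        inc["gni_pc"].to_numpy(), inc["gni_anchor"].to_numpy(), params
    )

    ratios = _life_ratios(region_allcause, params, age_groups)

    df = gaps.merge(inc[["region", "year", "gni_pc", "vsl"]], on=["region", "year"], how="left")
    if df["gni_pc"].isna().any():
        bad = df[df["gni_pc"].isna()].iloc[0]
        raise ValueError(f"income missing for region {bad['region']} year {bad['year']}")
    df = df.merge(ratios, on=["region", "sex", "year", "age_group"], how="left")
    df = df.merge(
        region_population, on=["region", "sex", "age_group", "year"], how="left"
    )
    df["v"] = value_of_reduction(
        df["delta"].to_numpy(),
        df["gni_pc"].to_numpy(),
        df["vsl"].to_numpy(),
        df["le_ratio"].to_numpy(),
    )

    keys = ["region", "sex", "cause", "year"]
    df["_pv"] = df["pop"] * df["v"]
    g = df.groupby(keys, sort=False)
    per_sex = (
        g.agg(_pv=("_pv", "sum"), _pop=("pop", "sum"), gni_pc=("gni_pc", "first"))
        .reset_index()
    )
    per_sex["absolute_value_pc"] = per_sex["_pv"] / per_sex["_pop"]
    per_sex["value_pct_income"] = 100.0 * per_sex["absolute_value_pc"] / per_sex["gni_pc"]

    both = (
        per_sex.groupby(["region", "cause", "year"], sort=False)
        .agg(_pv=("_pv", "sum"), _pop=("_pop", "sum"), gni_pc=("gni_pc", "first"))
        .reset_index()
        .assign(sex="both")
    )
    both["absolute_value_pc"] = both["_pv"] / both["_pop"]
    both["value_pct_income"] = 100.0 * both["absolute_value_pc"] / both["gni_pc"]
    out = pd.concat(
        [
            per_sex[["region", "sex", "cause", "year", "value_pct_income", "absolute_value_pc"]],
            both[["region", "sex", "cause", "year", "value_pct_income", "absolute_value_pc"]],
        ],
        ignore_index=True,
    )
    out["level"] = out["cause"].map({c: tree.node(c).level for c in tree.codes})
    return out.sort_values(["region", "cause", "sex", "year"], ignore_index=True)[
        ["region", "sex", "cause", "level", "year", "value_pct_income", "absolute_value_pc"]
    ]
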