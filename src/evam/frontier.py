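"""Mortality frontier estimation.

The frontier is the lowest-achieved mortality profile: for each age
group, cause and year, the 10th percentile (or, as a sensitivity variant,
the minimum) of the rates of eligible countries.  Eligibility screens out
small populations, missing income data and low-quality vital
registration, all of which inflate stochastic variability in the lowest
observed rates.

Frontiers are sexless except for breast and cervix uteri cancer: for all
other causes each eligible country contributes one pool value per sex
(both sexes pooled); for the two female-specific cancers the pool is the
female series and the male frontier is fixed at zero.

Because the percentile is taken cause by cause, cause frontiers do not
sum to the all-cause frontier; :func:`nested_rescale` restores additivity
level by level down the cause tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .causes import SEX_SPECIFIC_CAUSES, CauseTree

__all__ = [
    "EligibilityCriteria",
    "select_eligible_countries",
    "empirical_frontier",
    "nested_rescale",
    "check_nested_sums",
]

#: Quantile of the eligible-country pool defining the frontier.
FRONTIER_PERCENTILE = 0.10

_RTOL = 1e-9


@dataclass(frozen=True)
class EligibilityCriteria:
    """Screens applied to countries entering the frontier pool."""

    min_population: float = 5_000_000.0
    require_income: bool = True
    require_vr_quality: bool = True
    require_estimates: bool = True

    def __post_init__(self):
        if self.min_population <= 0:
            raise ValueError("min_population must be > 0")


def select_eligible_countries(
    population: pd.DataFrame,
    income: pd.DataFrame,
    metadata: pd.DataFrame,
    mortality: pd.DataFrame,
    criteria: EligibilityCriteria = EligibilityCriteria(),
    reference_year: int = 2019,
) -> list[str]:
    """Return iso3 codes of countries satisfying all active criteria."""
    pop_ref = population[population["year"] == reference_year]
    if pop_ref.empty:
        raise ValueError(f"population table does not cover {reference_year}")
    totals = pop_ref.groupby("iso3")["pop"].sum()
    eligible = set(totals[totals >= criteria.min_population].index)

    if criteria.require_income:
        with_income = set(
            income.loc[
                (income["year"] == reference_year) & income["gni_pc"].notna(), "iso3"
            ]
        )
        eligible &= with_income
    if criteria.require_vr_quality:
        good_vr = set(metadata.loc[metadata["vr_quality"].astype(bool), "iso3"])
        eligible &= good_vr
    if criteria.require_estimates:
        with_est = set(mortality.loc[mortality["year"] == reference_year, "iso3"])
        eligible &= with_est
    if not eligible:
        raise ValueError("no eligible countries")
    return sorted(eligible)


def _pool_stat(values: np.ndarray, method: str) -> float:
    if method == "minimum":
        return float(values.min())
    if method == "percentile_p10":
        # linear interpolation between order statistics, h = (n-1)p + 1
        return float(np.quantile(values, FRONTIER_PERCENTILE))
    raise ValueError(f"unknown frontier method: {method}")


def empirical_frontier(
    rates: pd.DataFrame,
    method: str = "percentile_p10",
    sex_specific: frozenset[str] = SEX_SPECIFIC_CAUSES,
) -> pd.DataFrame:
    """Raw (unscaled) frontier from eligible countries' rates.

    ``rates`` is a country-level long table (iso3, sex, age_group, cause,
    year, rate) already restricted to eligible countries; the caller
    decides eligibility.  Returns (age_group, sex, cause, year, value)
    with ``sex='both'`` for pooled causes.
    """
    if method not in ("percentile_p10", "minimum"):
        raise ValueError(f"unknown frontier method: {method}")
    if rates.empty:
        raise ValueError("empty pool: no rates supplied")

    pooled = rates[~rates["cause"].isin(sex_specific)]
    q = FRONTIER_PERCENTILE
    if method == "percentile_p10":
        agg = pooled.groupby(["age_group", "cause", "year"], sort=False)["rate"].quantile(q)
    else:
        agg = pooled.groupby(["age_group", "cause", "year"], sort=False)["rate"].min()
    out_pooled = agg.reset_index().rename(columns={"rate": "value"}).assign(sex="both")

    split = rates[rates["cause"].isin(sex_specific) & (rates["sex"] == "female")]
    if method == "percentile_p10":
        agg_f = split.groupby(["age_group", "cause", "year"], sort=False)["rate"].quantile(q)
    else:
        agg_f = split.groupby(["age_group", "cause", "year"], sort=False)["rate"].min()
    out_f = agg_f.reset_index().rename(columns={"rate": "value"}).assign(sex="female")
    out_m = out_f.assign(sex="male", value=0.0)

    out = pd.concat([out_pooled, out_f, out_m], ignore_index=True)
    return out[["age_group", "sex", "cause", "year", "value"]].sort_values(
        ["cause", "age_group", "sex", "year"], ignore_index=True
    )


def _infer_cells(df: pd.DataFrame, value_col: str, mixed_sex: bool) -> list[str]:
    drop = {"cause", value_col, "provenance"}
    if mixed_sex:
        drop.add("sex")
    return [c for c in df.columns if c not in drop]


def nested_rescale(
    df: pd.DataFrame,
    tree: CauseTree,
    target: pd.DataFrame | None = None,
    value_col: str = "value",
    mixed_sex: bool = False,
    cell_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rescale cause values level by level so children sum to parents.

    Level-1 siblings are multiplied by ``target / sum(siblings)`` within
    each cell; each deeper sibling set is then scaled to its (already
    rescaled) parent.  ``target`` defaults to the root rows of ``df``;
    an explicit target replaces the root values.

    With ``mixed_sex=True`` the frame carries sexless ('both') values for
    pooled causes and per-sex rows for the sex-specific causes; a
    sex-split child contributes its female value to the sexless sibling
    sum, and the resulting factor applies to both of its sex rows.

    The scale factor is 1 when both the sibling sum and the target are
    zero; a zero sibling sum under a positive target raises.
    """
    cells = list(cell_cols) if cell_cols is not None else _infer_cells(df, value_col, mixed_sex)
    root = tree.root.code
    out = df.copy()

    if target is not None:
        tgt = target.rename(columns={target.columns[-1]: value_col}) if value_col not in target.columns else target
        tgt = tgt[cells + [value_col]]
        # replace root rows with the target
        mask = out["cause"] == root
        root_rows = out[mask].drop(columns=[value_col]).merge(tgt, on=cells, how="left")
        if root_rows[value_col].isna().any():
            raise ValueError("all-cause target does not cover every cell")
        out = pd.concat([out[~mask], root_rows[out.columns]], ignore_index=True)

    for level in range(1, tree.max_level() + 1):
        parents = sorted(
            {
                tree.node(c).parent
                for c in tree.level_codes(level)
                if tree.node(c).parent is not None
            }
        )
        child_map = {c: tree.node(c).parent for c in tree.level_codes(level)}
        child_mask = out["cause"].isin(child_map)
        children = out[child_mask]
        if children.empty:
            continue

        contrib = children
        if mixed_sex:
            contrib = children[children["sex"] != "male"]
        sums = (
            contrib.assign(_parent=contrib["cause"].map(child_map))
            .groupby(["_parent"] + cells, sort=False)[value_col]
            .sum()
            .rename("_child_sum")
            .reset_index()
        )
        parent_rows = out[out["cause"].isin(parents)][cells + ["cause", value_col]]
        parent_rows = parent_rows.rename(columns={"cause": "_parent", value_col: "_target"})
        if mixed_sex:
            parent_rows = parent_rows.drop_duplicates(subset=["_parent"] + cells)
        fac = sums.merge(parent_rows, on=["_parent"] + cells, how="left")
        if fac["_target"].isna().any():
            missing = fac.loc[fac["_target"].isna(), "_parent"].unique()
            raise ValueError(f"missing parent values for rescale: {sorted(missing)}")

        cs = fac["_child_sum"].to_numpy(dtype=float)
        tg = fac["_target"].to_numpy(dtype=float)
        bad = (cs == 0) & (tg > 0)
        if bad.any():
            row = fac[bad].iloc[0]
            cell_desc = ", ".join(f"{k}={row[k]}" for k in cells)
            raise ValueError(
                f"unattributable mass: children of {row['_parent']} sum to 0 "
                f"but target is {row['_target']:g} at {cell_desc}"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where((cs == 0) & (tg == 0), 1.0, tg / cs)
        fac["_factor"] = factor

        upd = children.assign(_parent=children["cause"].map(child_map)).merge(
            fac[["_parent"] + cells + ["_factor"]], on=["_parent"] + cells, how="left"
        )
        new_vals = upd[value_col].to_numpy() * upd["_factor"].to_numpy()
        out = out.copy()
        out.loc[child_mask, value_col] = new_vals
    return out


def check_nested_sums(
    df: pd.DataFrame,
    tree: CauseTree,
    value_col: str = "value",
    mixed_sex: bool = False,
    rtol: float = _RTOL,
) -> float:
    """Max relative child-sum error across all parents and cells (for
    asserting the post-rescale consistency invariant)."""
    cells = _infer_cells(df, value_col, mixed_sex)
    worst = 0.0
    for parent in tree.parents_with_children():
        kids = tree.children(parent)
        rows = df[df["cause"].isin(kids)]
        if mixed_sex:
            rows = rows[rows["sex"] != "male"]
        sums = rows.groupby(cells, sort=False)[value_col].sum().rename("_s").reset_index()
        pr = df[df["cause"] == parent]
        if mixed_sex:
            pr = pr.drop_duplicates(subset=cells)
        merged = sums.merge(pr[cells + [value_col]], on=cells)
        denom = np.maximum(np.abs(merged[value_col].to_numpy()), 1e-300)
        rel = np.abs(merged["_s"].to_numpy() - merged[value_col].to_numpy()) / denom
        zero_both = (merged["_s"].to_numpy() == 0) & (merged[value_col].to_numpy() == 0)
        rel = np.where(zero_both, 0.0, rel)
        worst = max(worst, float(rel.max()) if len(rel) else 0.0)
    return worst
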