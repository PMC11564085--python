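"""Scenario configuration and pipeline orchestration.

A scenario is one full pass: frontier estimation -> trajectory projection
-> avoidable-mortality gaps -> economic valuation, with all intermediate
tables written as CSV.  The sensitivity suite reruns the pass across the
scenario grid (minimum-rate frontier; income elasticity 1.0 / 1.5; anchor
ratio 100 at the rich-region mean income; discount 1% / 5%), each variant
differing from the base case in exactly one setting.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .causes import CauseTree, build_default_tree, rollup_tree, validate_tree
from .frontier import EligibilityCriteria, empirical_frontier, nested_rescale, select_eligible_countries
from .gaps import aggregate_region, compute_gaps
from .io import file_sha256, read_table, write_table
from .projection import project_surface
from .valuation import ValuationParams, economic_value_share, project_income

__all__ = ["ScenarioConfig", "run_pipeline", "run_sensitivity_suite", "SENSITIVITY_SCENARIOS"]

log = logging.getLogger("evam")

SENSITIVITY_SCENARIOS = (
    "base",
    "frontier_min",
    "elasticity_low",
    "elasticity_high",
    "anchor_oecd100",
    "discount_1",
    "discount_5",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """One pipeline scenario (flat, YAML-serializable)."""

    mortality: str = "mortality.csv"
    population: str = "population.csv"
    income: str = "income.csv"
    income_growth: str | None = "income_growth.csv"
    metadata: str = "country_metadata.csv"
    cause_tree: str | None = None  # default Table-derived tree when None
    allcause_frontier: str | None = None  # optional external target file
    out_dir: str = "results/run"
    scenario: str = "base"
    frontier_method: str = "percentile_p10"
    fit_start: int = 2000
    fit_end: int = 2019
    horizon_end: int = 2050
    reference_year: int = 2019
    min_population: float = 5_000_000.0
    require_income: bool = True
    require_vr_quality: bool = True
    require_estimates: bool = True
    clamp_gaps: bool = True
    anchor_mode: str = "max_income"  # or "rich_region_mean"
    params: ValuationParams = field(default_factory=ValuationParams)
    report_years: tuple[int, ...] = (2000, 2019, 2050)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.fit_start >= self.fit_end:
            raise ValueError("fit window must span at least two years")
        if self.fit_end >= self.horizon_end:
            raise ValueError("fit window must precede the horizon")
        if self.anchor_mode not in ("max_income", "rich_region_mean"):
            raise ValueError(f"unknown anchor_mode: {self.anchor_mode}")

    @property
    def fit_window(self) -> tuple[int, int]:
        return (self.fit_start, self.fit_end)

    @property
    def horizon(self) -> tuple[int, int]:
        return (self.fit_end + 1, self.horizon_end)

    def criteria(self) -> EligibilityCriteria:
        return EligibilityCriteria(
            min_population=self.min_population,
            require_income=self.require_income,
            require_vr_quality=self.require_vr_quality,
            require_estimates=self.require_estimates,
        )

    # -- flat YAML round trip ---------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        p = d.pop("params")
        d.update({f"valuation_{k}": v for k, v in p.items()})
        d["report_years"] = list(self.report_years)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        pkeys = {
            k[len("valuation_"):]: d.pop(k) for k in list(d) if k.startswith("valuation_")
        }
        params = ValuationParams(**pkeys) if pkeys else ValuationParams()
        if "report_years" in d:
            d["report_years"] = tuple(d["report_years"])
        return cls(params=params, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class _EpiStage:
    """Everything upstream of the economics, shared across economic
    sensitivity scenarios."""

    tree: CauseTree
    eligible: list[str]
    frontier: pd.DataFrame  # mixed-sex, scaled, observed+projected
    country_surface: pd.DataFrame
    region_rates: pd.DataFrame
    gaps: pd.DataFrame
    region_income: pd.DataFrame
    region_population: pd.DataFrame
    region_allcause: pd.DataFrame
    country_income: pd.DataFrame
    metadata: pd.DataFrame


def _load_inputs(config: ScenarioConfig) -> dict:
    inputs = {
        "mortality": read_table(config.mortality, ["iso3", "sex", "age_group", "cause", "year", "rate"]),
        "population": read_table(config.population, ["iso3", "sex", "age_group", "year", "pop"]),
        "income": read_table(config.income, ["iso3", "year", "gni_pc"]),
        "metadata": read_table(config.metadata, ["iso3", "region", "vr_quality"]),
    }
    if config.income_growth:
        inputs["income_growth"] = read_table(config.income_growth, ["iso3", "growth_rate"])
    if config.cause_tree:
        inputs["tree"] = CauseTree.from_frame(read_table(config.cause_tree))
    else:
        inputs["tree"] = build_default_tree()
    rep = validate_tree(inputs["tree"])
    if not rep.ok:
        raise ValueError(f"invalid cause tree: {rep.violations}")
    if config.allcause_frontier:
        inputs["allcause_frontier"] = read_table(
            config.allcause_frontier, ["age_group", "sex", "year", "value"]
        )
    return inputs


def _epi_stage(config: ScenarioConfig, inputs: dict) -> _EpiStage:
    tree = inputs["tree"]
    mortality = inputs["mortality"]
    population = inputs["population"]
    income = inputs["income"]
    metadata = inputs["metadata"]

    # full income coverage through the horizon
    if income["year"].max() < config.horizon_end:
        if "income_growth" not in inputs:
            raise ValueError(
                "income table ends before the horizon and no growth-rate table given"
            )
        income = project_income(
            income,
            inputs["income_growth"],
            config.horizon_end,
            base_year=int(income["year"].max()),
        )

    eligible = select_eligible_countries(
        population, income, metadata, mortality,
        criteria=config.criteria(), reference_year=config.reference_year,
    )
    log.info("eligible countries for frontier: %d", len(eligible))

    surface = rollup_tree(
        mortality[["iso3", "sex", "age_group", "cause", "year", "rate"]], tree
    )

    # frontier: raw percentile/minimum, rescaled per observed year, fitted
    # and projected, rescaled per horizon year
    elig_rates = surface[surface["iso3"].isin(eligible)].drop(columns="iso3")
    raw = empirical_frontier(elig_rates, method=config.frontier_method)
    target_obs = None
    if "allcause_frontier" in inputs:
        ext = inputs["allcause_frontier"]
        target_obs = ext[(ext["year"] >= config.fit_start) & (ext["year"] <= config.fit_end)]
        target_obs = target_obs[["age_group", "year", "value"]]
    elif config.frontier_method != "percentile_p10":
        # the sensitivity frontier changes the cause-specific pools only;
        # scaling stays anchored to the reference all-cause frontier
        ref = empirical_frontier(
            elig_rates[elig_rates["cause"] == tree.root.code], method="percentile_p10"
        )
        target_obs = ref[["age_group", "year", "value"]]
    scaled_obs = nested_rescale(raw, tree, target=target_obs, mixed_sex=True)

    target_proj = None
    if "allcause_frontier" in inputs:
        ext = inputs["allcause_frontier"]
        target_proj = ext[(ext["year"] > config.fit_end)][["age_group", "year", "value"]]
        if target_proj.empty:
            target_proj = None
    frontier_full = project_surface(
        scaled_obs,
        cell_cols=["age_group", "sex", "cause"],
        fit_window=config.fit_window,
        horizon=config.horizon,
        tree=tree,
        allcause_target=target_proj,
        value_col="value",
        mixed_sex=True,
    )

    # country surfaces: fit, project, rescale to own all-cause projection
    country_full = project_surface(
        surface,
        cell_cols=["iso3", "sex", "age_group", "cause"],
        fit_window=config.fit_window,
        horizon=config.horizon,
        tree=tree,
        value_col="rate",
    )

    region_map = dict(zip(metadata["iso3"], metadata["region"]))
    region_rates = aggregate_region(
        country_full.drop(columns="provenance"), population, region_map
    )
    gaps = compute_gaps(region_rates, frontier_full, clamp=config.clamp_gaps)

    # region income (population-weighted GNI per capita) and populations
    pop_tot = population.groupby(["iso3", "year"], sort=False)["pop"].sum().reset_index()
    inc = income.merge(pop_tot, on=["iso3", "year"], how="inner")
    inc["region"] = inc["iso3"].map(region_map)
    inc["_wy"] = inc["gni_pc"] * inc["pop"]
    g = inc.groupby(["region", "year"], sort=False)
    region_income = (g["_wy"].sum() / g["pop"].sum()).rename("gni_pc").reset_index()

    pop_region = population.copy()
    pop_region["region"] = pop_region["iso3"].map(region_map)
    region_population = (
        pop_region.groupby(["region", "sex", "age_group", "year"], sort=False)["pop"]
        .sum()
        .reset_index()
    )
    region_allcause = region_rates[region_rates["cause"] == tree.root.code][
        ["region", "sex", "age_group", "year", "rate"]
    ]

    return _EpiStage(
        tree=tree,
        eligible=eligible,
        frontier=frontier_full,
        country_surface=country_full,
        region_rates=region_rates,
        gaps=gaps,
        region_income=region_income,
        region_population=region_population,
        region_allcause=region_allcause,
        country_income=income,
        metadata=metadata,
    )


def _anchor_income(epi: _EpiStage, config: ScenarioConfig) -> pd.DataFrame:
    """Anchor economy's GNI per capita by year, per anchor mode."""
    inc = epi.country_income
    ref = inc[inc["year"] == config.reference_year]
    anchor_iso = ref.loc[ref["gni_pc"].idxmax(), "iso3"]
    if config.anchor_mode == "max_income":
        out = inc[inc["iso3"] == anchor_iso][["year", "gni_pc"]]
    else:  # unweighted mean of the anchor country's region (OECD-mean stand-in)
        region = dict(zip(epi.metadata["iso3"], epi.metadata["region"]))[anchor_iso]
        members = [i for i, r in zip(epi.metadata["iso3"], epi.metadata["region"]) if r == region]
        out = (
            inc[inc["iso3"].isin(members)]
            .groupby("year", sort=False)["gni_pc"]
            .mean()
            .reset_index()
        )
    return out.reset_index(drop=True)


def _value_stage(epi: _EpiStage, config: ScenarioConfig) -> pd.DataFrame:
    anchor = _anchor_income(epi, config)
    values = economic_value_share(
        epi.gaps[["region", "sex", "age_group", "cause", "year", "delta"]],
        epi.region_income,
        epi.region_population,
        epi.region_allcause,
        anchor,
        config.params,
        epi.tree,
    )
    values.insert(0, "scenario", config.scenario)
    return values


def _rates_of_change(values: pd.DataFrame, report_years: tuple[int, ...]) -> pd.DataFrame:
    """Annualized %/yr change of value shares between consecutive report years."""
    rows = []
    yrs = sorted(report_years)
    pivot = values.pivot_table(
        index=["scenario", "region", "sex", "cause", "level"],
        columns="year",
        values="value_pct_income",
        aggfunc="first",
    )
    for t1, t2 in zip(yrs[:-1], yrs[1:]):
        if t1 not in pivot.columns or t2 not in pivot.columns:
            continue
        v1, v2 = pivot[t1], pivot[t2]
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = 100.0 * ((v2 / v1) ** (1.0 / (t2 - t1)) - 1.0)
        rate = rate.where(v1 > 0)
        part = pivot.reset_index()[["scenario", "region", "sex", "cause", "level"]].copy()
        part["period"] = f"{t1}-{t2}"
        part["pct_per_year"] = rate.to_numpy()
        rows.append(part)
    if not rows:
        return pd.DataFrame(
            columns=["scenario", "region", "sex", "cause", "level", "period", "pct_per_year"]
        )
    return pd.concat(rows, ignore_index=True)


def _write_manifest(config: ScenarioConfig, out: Path) -> None:
    checksums = {}
    for key in ("mortality", "population", "income", "income_growth", "metadata",
                "cause_tree", "allcause_frontier"):
        p = getattr(config, key)
        if p and Path(p).exists():
            checksums[key] = file_sha256(p)
    manifest = {"inputs_sha256": checksums, "config": config.to_dict()}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def run_pipeline(config: ScenarioConfig, stop_after: str | None = None) -> dict:
    """Execute one scenario end to end; returns the artifact frames.

    ``stop_after`` in {"frontier", "project", None} truncates the run for
    the corresponding CLI subcommands.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = _load_inputs(config)
    log.info("scenario %s: frontier method %s", config.scenario, config.frontier_method)

    epi = _epi_stage(config, inputs)
    frontier_out = epi.frontier.assign(method=config.frontier_method, scaled=True)
    write_table(
        frontier_out[["age_group", "sex", "cause", "year", "method", "scaled", "value", "provenance"]],
        out / "frontier.csv",
    )
    artifacts = {"frontier": epi.frontier, "eligible": epi.eligible}
    if stop_after == "frontier":
        _write_manifest(config, out)
        return artifacts

    write_table(epi.country_surface, out / "country_projections.csv")
    write_table(epi.region_rates, out / "region_rates.csv")
    artifacts["country_surface"] = epi.country_surface
    artifacts["region_rates"] = epi.region_rates
    if stop_after == "project":
        _write_manifest(config, out)
        return artifacts

    write_table(epi.gaps, out / "avoidable_gaps.csv")
    values = _value_stage(epi, config)
    write_table(values, out / "economic_value.csv")
    changes = _rates_of_change(values, config.report_years)
    write_table(changes, out / "value_rates_of_change.csv")
    _write_manifest(config, out)
    artifacts.update({"gaps": epi.gaps, "values": values, "changes": changes, "_epi": epi})
    return artifacts


def scenario_variants(base: ScenarioConfig) -> list[ScenarioConfig]:
    """The seven-scenario grid, each differing from base in one setting."""
    p = base.params
    out_root = Path(base.out_dir)
    mk = lambda label, **kw: replace(
        base, scenario=label, out_dir=str(out_root / label), **kw
    )
    return [
        mk("base"),
        mk("frontier_min", frontier_method="minimum"),
        mk("elasticity_low", params=p.with_elasticity(1.0)),
        mk("elasticity_high", params=p.with_elasticity(1.5)),
        mk(
            "anchor_oecd100",
            params=replace(p, vsl_anchor_ratio=100.0),
            anchor_mode="rich_region_mean",
        ),
        mk("discount_1", params=replace(p, discount_rate=0.01)),
        mk("discount_5", params=replace(p, discount_rate=0.05)),
    ]


def run_sensitivity_suite(base: ScenarioConfig) -> pd.DataFrame:
    """Run the base case plus six univariate variants; returns the
    combined long table of value shares (written to sensitivity.csv)."""
    logging.basicConfig(level=getattr(logging, base.log_level.upper(), logging.INFO))
    inputs = _load_inputs(base)
    epi_cache: dict[str, _EpiStage] = {}
    frames = []
    for cfg in scenario_variants(base):
        key = cfg.frontier_method
        if key not in epi_cache:
            epi_cache[key] = _epi_stage(cfg, inputs)
        epi = epi_cache[key]
        log.info("sensitivity scenario: %s", cfg.scenario)
        values = _value_stage(epi, cfg)
        frames.append(values)
    combined = pd.concat(frames, ignore_index=True)
    out = Path(base.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(combined, out / "sensitivity.csv")
    return combined
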