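"""Synthetic multi-country world with known ground truth.

Generates the three inputs the pipeline consumes — cause-specific death
rates, populations and GNI per capita — for a configurable set of
countries, together with the *truth*: the noiseless mortality frontier and
the log-linear trend coefficients every rate follows by construction.

The world is built so that the statistical model the pipeline assumes is
exactly correct:

* the true frontier declines log-linearly in time, with age-specific
  annual log-slopes shared across causes within an age band (the cause
  composition of the frontier is constant over time, so parents of the
  cause tree are log-linear whenever their children are);
* country rates are the frontier times a country–cause multiplicative
  spread (>= 1, equal to 1 for the designated frontier countries) times
  i.i.d. multiplicative lognormal noise;
* male rates carry a constant multiplier > 1, except breast and cervix
  uteri cancer, which are structurally zero for males.

Regenerating with the same :class:`WorldConfig` is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .causes import SEX_SPECIFIC_CAUSES, CauseTree, build_default_tree, rollup_tree

__all__ = [
    "DEFAULT_AGE_GROUPS",
    "REGION_NAMES",
    "WorldConfig",
    "WorldData",
    "age_group_midpoints",
    "age_group_widths",
    "generate_world",
    "world_truth",
]

DEFAULT_AGE_GROUPS: tuple[str, ...] = (
    "0-1",
    "1-4",
    *(f"{a}-{a + 4}" for a in range(5, 85, 5)),
    "85+",
)

REGION_NAMES = (
    "high_income",
    "upper_middle_a",
    "upper_middle_b",
    "lower_middle_a",
    "lower_middle_b",
    "low_income",
)

#: Open age interval is closed at this age for life-table purposes.
LIFE_TABLE_CAP = 100.0


def _age_bounds(group: str) -> tuple[float, float]:
    """[lo, hi) bounds of an age-group label.  '0-1' is the infant group
    [0, 1); other 'a-b' labels span [a, b+1); 'a+' runs to the cap."""
    if group.endswith("+"):
        return float(group[:-1]), LIFE_TABLE_CAP
    lo, hi = group.split("-")
    lo, hi = float(lo), float(hi)
    if lo == 0.0 and hi == 1.0:
        return 0.0, 1.0
    return lo, hi + 1.0


def age_group_midpoints(age_groups: tuple[str, ...] = DEFAULT_AGE_GROUPS) -> np.ndarray:
    return np.asarray([(lo + hi) / 2.0 for lo, hi in map(_age_bounds, age_groups)])


def age_group_widths(age_groups: tuple[str, ...] = DEFAULT_AGE_GROUPS) -> np.ndarray:
    return np.asarray([hi - lo for lo, hi in map(_age_bounds, age_groups)])


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of the synthetic world.

    Defaults define the reference study conditions: 20 countries, of which
    the 10 richest sit exactly on the frontier, years 2000–2019 observed
    and 2020–2050 horizon, 5% multiplicative lognormal noise on rates, and
    incomes spanning three orders of magnitude so the VSL floor can bind.
    """

    seed: int = 0
    n_countries: int = 20
    n_frontier: int = 10
    years: tuple[int, int] = (2000, 2050)
    observed_end: int = 2019
    age_groups: tuple[str, ...] = DEFAULT_AGE_GROUPS
    noise_sd: float = 0.05
    sex_multiplier: float = 1.4
    #: country spread = (anchor_income / income)^spread_exponent, jittered
    #: per cause; frontier countries are exactly 1.
    spread_exponent: float = 0.35
    spread_jitter_sd: float = 0.2
    income_anchor: float = 70_000.0
    income_floor: float = 900.0
    pop_max: float = 1.5e8
    pop_min: float = 3.0e6
    low_vr_indices: tuple[int, ...] = (12, 15)
    #: optional overrides: frame (age_group, cause[, sex], level_2000, slope)
    frontier_params: pd.DataFrame | None = None
    #: optional override: frame (iso3, cause, spread)
    country_spread: pd.DataFrame | None = None
    vr_quality: tuple[bool, ...] | None = None
    tree: CauseTree | None = None
    #: zero out the female-specific cancers entirely (used by the null
    #: world: with sex-pooled frontiers, a world with female-only cancer
    #: mass cannot sit on the frontier for both sexes at cancer ancestors)
    zero_sex_specific: bool = False

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.n_frontier <= self.n_countries):
            raise ValueError("n_frontier must be in (0, n_countries]")
        if self.years[0] > self.observed_end or self.observed_end > self.years[1]:
            raise ValueError("need years[0] <= observed_end <= years[1]")

    def cause_tree(self) -> CauseTree:
        return self.tree if self.tree is not None else build_default_tree()

    @classmethod
    def frontier_world(cls, seed: int = 0, **kwargs) -> "WorldConfig":
        """A world in which every country (and both sexes) sits exactly on
        the frontier: no spread, no noise, no male excess."""
        return cls(
            seed=seed,
            noise_sd=0.0,
            sex_multiplier=1.0,
            spread_exponent=0.0,
            spread_jitter_sd=0.0,
            zero_sex_specific=True,
            **kwargs,
        )


@dataclass
class WorldData:
    """Generated inputs plus ground truth."""

    config: WorldConfig
    mortality: pd.DataFrame  # country,iso3,sex,age_group,cause,year,rate (leaf causes)
    population: pd.DataFrame  # country,iso3,sex,age_group,year,pop
    income: pd.DataFrame  # iso3,year,gni_pc  (full 2000-2050 truth)
    income_growth: pd.DataFrame  # iso3,growth_rate (rich-country subset)
    metadata: pd.DataFrame  # country,iso3,region,vr_quality,frontier_country
    truth_frontier: pd.DataFrame  # age_group,sex,cause,year,value (all tree nodes)
    truth_trends: pd.DataFrame  # age_group,sex,cause,intercept,slope (leaves)

    def write_csvs(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the pipeline's input files (income truncated at 2021, the
        WDI-style observation window) plus the truth, in fixed dialects."""
        from .io import write_table

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        income_obs = self.income[self.income["year"] <= 2021]
        paths = {
            "mortality": write_table(self.mortality, out / "mortality.csv"),
            "population": write_table(self.population, out / "population.csv"),
            "income": write_table(income_obs, out / "income.csv"),
            "income_growth": write_table(self.income_growth, out / "income_growth.csv"),
            "metadata": write_table(self.metadata, out / "country_metadata.csv"),
            "cause_tree": write_table(
                self.config.cause_tree().to_frame(), out / "cause_tree.csv"
            ),
            "truth_frontier": write_table(self.truth_frontier, out / "truth_frontier.csv"),
            "truth_trends": write_table(self.truth_trends, out / "truth_trends.csv"),
        }
        return paths


# ---------------------------------------------------------------------------
# frontier truth


def _default_level1_shares(mid: np.ndarray) -> pd.DataFrame:
    """Age-varying level-1 cause composition of the frontier."""
    comm = 0.65 * np.exp(-mid / 15.0) + 0.04
    inj = 0.25 * np.exp(-(((mid - 22.0) / 25.0) ** 2)) + 0.02
    ncd = 1.0 - comm - inj
    return pd.DataFrame(
        {
            "communicable_maternal_perinatal_and_nutritional_conditions": comm,
            "ncds": ncd,
            "injuries": inj,
        }
    )


# Conditional shares within each parent (constant across ages); leaves of
# level 2 without children are their own mass.
_L2_SHARES = {
    "infectious_and_parasitic_diseases": 0.55,
    "maternal_and_neonatal_conditions": 0.35,
    "nutritional_deficiencies": 0.10,
    "cvds": 0.40,
    "diabetes_mellitus": 0.05,
    "digestive_diseases": 0.07,
    "malignant_neoplasms": 0.25,
    "respiratory_diseases": 0.09,
    "other_ncds": 0.14,
    "intentional_injuries": 0.35,
    "unintentional_injuries": 0.65,
}
_L3_SHARES = {
    "ischemic_heart_disease": 0.50,
    "stroke": 0.35,
    "other_cvds": 0.15,
    "cirrhosis_of_the_liver": 0.55,
    "other_digestive_diseases": 0.45,
    "breast_cancer": 0.15,
    "cervix_uteri_cancer": 0.08,
    "liver_cancer": 0.10,
    "mouth_and_oropharynx_cancers": 0.06,
    "esophagus_cancer": 0.07,
    "stomach_cancer": 0.11,
    "trachea_bronchus_and_lung_cancers": 0.20,
    "other_malignant_neoplasms": 0.23,
    "chronic_obstructive_pulmonary_disease": 0.60,
    "other_respiratory_diseases": 0.40,
    "road_injury": 0.45,
    "other_unintentional_injuries": 0.55,
}


def _allcause_frontier_2000(mid: np.ndarray) -> np.ndarray:
    """All-cause frontier death rate in 2000 by age midpoint (J-shape)."""
    rate = 1.6e-4 * np.exp(0.072 * (mid - 7.5))
    rate = np.where(mid < 1.0, 3.5e-3, rate)
    rate = np.where((mid >= 1.0) & (mid < 5.0), 2.5e-4, rate)
    return rate


def _frontier_slopes(mid: np.ndarray) -> np.ndarray:
    """Annual log-slope of the frontier by age (faster declines young)."""
    return -0.022 + 0.00018 * mid


def _leaf_share_table(config: WorldConfig) -> pd.DataFrame:
    """Per age_group x leaf cause: share of the all-cause frontier (female
    reference profile; male zeros for sex-specific causes are applied in
    the truth builder)."""
    tree = config.cause_tree()
    mid = age_group_midpoints(config.age_groups)
    l1 = _default_level1_shares(mid)
    rows = []
    for leaf in tree.leaves:
        node = tree.node(leaf)
        share = 1.0
        code = leaf
        while tree.node(code).parent is not None:
            if tree.node(code).level == 3:
                share *= _L3_SHARES[code]
            elif tree.node(code).level == 2:
                share *= _L2_SHARES[code]
            code = tree.node(code).parent
        # share now conditional within its level-1 ancestor
        l1_code = leaf
        while tree.node(l1_code).level > 1:
            l1_code = tree.node(l1_code).parent
        for i, ag in enumerate(config.age_groups):
            rows.append((ag, leaf, share * l1[l1_code].iloc[i]))
    return pd.DataFrame(rows, columns=["age_group", "cause", "share"])


def _frontier_leaf_params(config: WorldConfig) -> pd.DataFrame:
    """(age_group, cause, level_2000, slope) for every leaf, female profile."""
    if config.frontier_params is not None:
        fp = config.frontier_params.copy()
        if (fp["level_2000"] <= 0).any():
            raise ValueError("frontier level_2000 parameters must be positive")
        return fp
    mid = age_group_midpoints(config.age_groups)
    base = pd.DataFrame(
        {
            "age_group": list(config.age_groups),
            "allcause_2000": _allcause_frontier_2000(mid),
            "slope": _frontier_slopes(mid),
        }
    )
    shares = _leaf_share_table(config)
    out = shares.merge(base, on="age_group")
    out["level_2000"] = out["allcause_2000"] * out["share"]
    return out[["age_group", "cause", "level_2000", "slope"]]


def _truth_leaf_rates(config: WorldConfig) -> pd.DataFrame:
    """Noiseless per-sex leaf frontier rates for all years in range.

    Female rows carry the reference profile; male rows are the female
    profile times the sex multiplier, zero for sex-specific causes.
    """
    params = _frontier_leaf_params(config)
    years = np.arange(config.years[0], config.years[1] + 1)
    y0 = config.years[0]
    grid = params.merge(pd.DataFrame({"year": years}), how="cross")
    grid["value"] = grid["level_2000"] * np.exp(grid["slope"] * (grid["year"] - y0))

    female = grid.assign(sex="female")
    if config.zero_sex_specific:
        female.loc[female["cause"].isin(SEX_SPECIFIC_CAUSES), "value"] = 0.0
    male = grid.assign(sex="male")
    male["value"] = male["value"] * config.sex_multiplier
    male.loc[male["cause"].isin(SEX_SPECIFIC_CAUSES), "value"] = 0.0
    out = pd.concat([female, male], ignore_index=True)
    return out[["age_group", "sex", "cause", "year", "value"]]


def world_truth(config: WorldConfig) -> pd.DataFrame:
    """The noiseless true frontier for every tree node and year.

    Returned in the frontier-surface layout: sexless (``sex='both'``)
    values for all causes except breast/cervix cancer, which keep separate
    female and male (zero) rows.  Internal nodes are sums of their
    children, with sex-specific children contributing their female value
    to sexless parents.  Independent of seed and noise level.
    """
    tree = config.cause_tree()
    leaves = _truth_leaf_rates(config)
    female = leaves[leaves["sex"] == "female"].drop(columns="sex")
    full = rollup_tree(female, tree, value_col="value")
    full = full.assign(sex="both")
    pooled = full[~full["cause"].isin(SEX_SPECIFIC_CAUSES)]
    split = leaves[leaves["cause"].isin(SEX_SPECIFIC_CAUSES)]
    out = pd.concat(
        [
            pooled[["age_group", "sex", "cause", "year", "value"]],
            split[["age_group", "sex", "cause", "year", "value"]],
        ],
        ignore_index=True,
    )
    return out.sort_values(["cause", "age_group", "sex", "year"], ignore_index=True)


# ---------------------------------------------------------------------------
# world assembly


def _country_table(config: WorldConfig) -> pd.DataFrame:
    n = config.n_countries
    idx = np.arange(n)
    iso3 = np.array([f"C{i:02d}" for i in idx])
    names = np.array([f"Country {i:02d}" for i in idx])
    # incomes descend log-linearly from the anchor to the floor
    if n > 1:
        gni_2021 = config.income_anchor * (
            (config.income_floor / config.income_anchor) ** (idx / (n - 1))
        )
    else:
        gni_2021 = np.array([config.income_anchor])
    region = np.empty(n, dtype=object)
    for r, block in zip(REGION_NAMES, np.array_split(idx, len(REGION_NAMES))):
        region[block] = r
    vr = np.ones(n, dtype=bool)
    if config.vr_quality is not None:
        vr = np.asarray(config.vr_quality, dtype=bool)
    else:
        for i in config.low_vr_indices:
            if i < n:
                vr[i] = False
    pop_2019 = np.geomspace(config.pop_max, config.pop_min, n) if n > 1 else np.array(
        [config.pop_max]
    )
    return pd.DataFrame(
        {
            "country": names,
            "iso3": iso3,
            "region": region,
            "vr_quality": vr,
            "frontier_country": idx < config.n_frontier,
            "gni_2021": gni_2021,
            "pop_2019": pop_2019,
        }
    )


def _country_spread(config: WorldConfig, countries: pd.DataFrame, rng) -> pd.DataFrame:
    """Multiplicative distance from the frontier per country x leaf cause."""
    if config.country_spread is not None:
        cs = config.country_spread.copy()
        if (cs["spread"] < 1.0 - 1e-12).any():
            raise ValueError("country spread multipliers must be >= 1")
        return cs
    tree = config.cause_tree()
    leaves = tree.leaves
    rows = []
    for _, c in countries.iterrows():
        if c["frontier_country"]:
            spread = np.ones(len(leaves))
        else:
            base = (config.income_anchor / c["gni_2021"]) ** config.spread_exponent
            jitter = np.exp(rng.normal(0.0, config.spread_jitter_sd, size=len(leaves)))
            spread = np.maximum(1.0, base * jitter)
        rows.append(pd.DataFrame({"iso3": c["iso3"], "cause": leaves, "spread": spread}))
    return pd.concat(rows, ignore_index=True)


def _population(config: WorldConfig, countries: pd.DataFrame) -> pd.DataFrame:
    mids = age_group_midpoints(config.age_groups)
    widths = age_group_widths(config.age_groups)
    years = np.arange(config.years[0], config.years[1] + 1)
    n = len(countries)
    rho = np.linspace(0.008, 0.038, n)  # rich: flat pyramid, poor: young
    g_pop = np.linspace(0.002, 0.025, n)
    frames = []
    for i, c in countries.reset_index(drop=True).iterrows():
        w = widths * np.exp(-rho[i] * mids)
        shares = w / w.sum()
        for sex in ("female", "male"):
            grid = pd.DataFrame(
                {
                    "country": c["country"],
                    "iso3": c["iso3"],
                    "sex": sex,
                    "age_group": np.repeat(config.age_groups, len(years)),
                    "year": np.tile(years, len(config.age_groups)),
                }
            )
            tot = c["pop_2019"] * (1.0 + g_pop[i]) ** (grid["year"] - 2019)
            grid["pop"] = 0.5 * tot * np.repeat(shares, len(years))
            frames.append(grid)
    return pd.concat(frames, ignore_index=True)


def _income(config: WorldConfig, countries: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full-coverage income truth plus the growth-rate table.

    The richest half of countries ("listed" economies) have an explicit
    growth rate; everyone else grows at the average of the listed rates —
    the same fallback rule the pipeline's income projection applies, so
    projecting the truncated series recovers the truth exactly.
    """
    n = len(countries)
    n_listed = max(1, n // 2)
    listed_rates = np.linspace(0.010, 0.025, n_listed)
    world_avg = float(listed_rates.mean())
    growth = np.full(n, world_avg)
    growth[:n_listed] = listed_rates
    years = np.arange(config.years[0], config.years[1] + 1)
    rows = []
    for i, c in countries.reset_index(drop=True).iterrows():
        gni = c["gni_2021"] * (1.0 + growth[i]) ** (years - 2021)
        rows.append(pd.DataFrame({"iso3": c["iso3"], "year": years, "gni_pc": gni}))
    income = pd.concat(rows, ignore_index=True)
    growth_tbl = pd.DataFrame(
        {"iso3": countries["iso3"].iloc[:n_listed], "growth_rate": listed_rates}
    )
    return income, growth_tbl


def generate_world(config: WorldConfig) -> WorldData:
    """Generate the synthetic world (deterministic in ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    tree = config.cause_tree()
    countries = _country_table(config)
    spread = _country_spread(config, countries, rng)
    # observed mortality only (the GHE-style input window)
    leaves = _truth_leaf_rates(config)
    leaves = leaves[leaves["year"] <= config.observed_end]

    # country x (sex, age, leaf cause, year) rates
    base = leaves.merge(spread, on="cause", how="inner")  # cross via cause
    base = base.merge(countries[["iso3", "country"]], on="iso3")
    rate = base["value"].to_numpy() * base["spread"].to_numpy()
    if config.noise_sd > 0:
        noise = np.exp(rng.normal(0.0, config.noise_sd, size=len(base)))
        rate = rate * noise
    base["rate"] = rate
    mortality = base[["country", "iso3", "sex", "age_group", "cause", "year", "rate"]]
    mortality = mortality.sort_values(
        ["iso3", "sex", "age_group", "cause", "year"], ignore_index=True
    )

    population = _population(config, countries)
    income, growth_tbl = _income(config, countries)
    metadata = countries[["country", "iso3", "region", "vr_quality", "frontier_country"]]

    truth = world_truth(config)
    params = _frontier_leaf_params(config)
    y0 = config.years[0]
    trends = params.rename(columns={"level_2000": "level_start"}).assign(
        intercept=lambda d: np.log(d["level_start"]), reference_year=y0
    )[["age_group", "cause", "intercept", "slope", "reference_year"]]

    return WorldData(
        config=config,
        mortality=mortality,
        population=population,
        income=income,
        income_growth=growth_tbl,
        metadata=metadata.copy(),
        truth_frontier=truth,
        truth_trends=trends,
    )
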