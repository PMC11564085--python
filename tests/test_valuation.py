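"""VSL extrapolation, discounted remaining life, concave valuation, shares."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evam.causes import build_default_tree
from evam.valuation import (
    ValuationParams,
    annualized_change,
    discounted_remaining_life,
    economic_value_share,
    extrapolate_vsl,
    project_income,
    value_of_reduction,
)

P = ValuationParams()


class TestExtrapolateVSL:
    def test_anchor_country_gets_anchor_ratio(self):
        assert extrapolate_vsl(70_000, 70_000, P) == pytest.approx(160 * 70_000)

    def test_half_income_below_anchor_elasticity_1_2(self):
        gni = 35_000.0
        vsl = extrapolate_vsl(gni, 70_000.0, P)
        assert vsl / gni == pytest.approx(160 * 0.5**0.2, rel=1e-12)
        assert vsl / gni == pytest.approx(139.3, abs=0.05)

    def test_floor_binds_under_high_elasticity(self):
        params = P.with_elasticity(1.5)
        gni = 700.0  # 1% of anchor; unfloored ratio 160*0.1 = 16 < 20
        vsl = extrapolate_vsl(gni, 70_000.0, params)
        assert vsl / gni == pytest.approx(20.0, rel=1e-12)

    def test_rich_side_uses_low_elasticity(self):
        vsl = extrapolate_vsl(140_000.0, 70_000.0, P)
        assert vsl == pytest.approx(160 * 70_000 * 2**0.8, rel=1e-12)

    def test_nonpositive_income_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_vsl(0.0, 70_000.0, P)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ValuationParams(discount_rate=1.5)
        with pytest.raises(ValueError):
            ValuationParams(vsl_anchor_ratio=-1)


def flat_schedule(rate, age_groups=("0-1", "1-4", "5-9")):
    return pd.Series(rate, index=list(age_groups))


class TestDiscountedRemainingLife:
    def test_no_mortality_no_discount_is_years_to_cap(self):
        drl = discounted_remaining_life(flat_schedule(0.0), 40.0, 0.0, cap=100.0)
        assert drl == pytest.approx(60.0, rel=1e-12)

    def test_huge_discount_keeps_first_year_only(self):
        drl = discounted_remaining_life(flat_schedule(0.01), 40.0, 1e9, cap=100.0)
        assert drl == pytest.approx(1.0, rel=1e-6)

    def test_constant_hazard_geometric_series_oracle(self):
        mu, r, a0, cap = 0.02, 0.03, 50.0, 100.0
        t = np.arange(int(cap - a0))
        oracle = np.sum(np.exp(-mu * t) * (1 + r) ** (-t.astype(float)))
        drl = discounted_remaining_life(flat_schedule(mu), a0, r, cap=cap)
        assert drl == pytest.approx(oracle, rel=1e-12)

    def test_strictly_decreasing_in_discount_rate(self):
        vals = [
            discounted_remaining_life(flat_schedule(0.01), 40.0, r) for r in (0.0, 0.01, 0.03, 0.05)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_fractional_start_age_splits_exposure(self):
        # from age 92.5 with hazard mu the first year spans one cell only
        # (flat schedule), so the closed form still applies
        mu = 0.1
        drl = discounted_remaining_life(flat_schedule(mu), 92.5, 0.0, cap=100.0)
        t = np.arange(8)  # 7.5 years -> 8 yearly terms, last partial
        # survival to the start of each lived year under constant hazard
        haz = np.minimum(1.0, np.maximum(0.0, 100.0 - (92.5 + t)))
        cum = np.concatenate([[0.0], np.cumsum(haz[:-1] * mu)])
        assert drl == pytest.approx(np.sum(np.exp(-cum)), rel=1e-12)


class TestValueOfReduction:
    def test_zero_gap_zero_value(self):
        assert value_of_reduction(0.0, 50_000.0, 160 * 50_000.0) == 0.0

    def test_small_risk_limit_matches_linear_vsl_within_1pct(self):
        y = 50_000.0
        v = value_of_reduction(1e-4, y, 160 * y)
        linear = 160 * y * 1e-4
        assert v / y == pytest.approx(1 - np.exp(-0.016), rel=1e-12)
        assert abs(v - linear) / linear < 0.01

    def test_bounded_by_income(self):
        y = 1000.0
        assert value_of_reduction(1.0, y, 160 * y) <= y
        # strict at any resolvable exponent
        assert value_of_reduction(1.0, y, 5 * y) < y

    @given(
        st.floats(min_value=0.0, max_value=0.5),
        st.floats(min_value=0.0, max_value=0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_subadditive_in_delta(self, d1, d2):
        y, vsl = 10_000.0, 500_000.0
        v = lambda d: value_of_reduction(d, y, vsl)
        assert v(d1 + d2) <= v(d1) + v(d2) + 1e-12

    def test_linear_limit_recovers_constant_vsl(self):
        y, vsl, d = 20_000.0, 160 * 20_000.0, 0.01
        ratios = [value_of_reduction(eps * d, y, vsl) / eps for eps in (1e-3, 1e-5, 1e-7)]
        assert ratios[-1] == pytest.approx(vsl * d, rel=1e-5)

    def test_delta_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            value_of_reduction(1.5, 1000.0, 20_000.0)


class TestAnnualizedChange:
    def test_no_change_is_zero(self):
        assert annualized_change(5.0, 5.0, 2000, 2019) == pytest.approx(0.0)

    def test_doubling_over_19_years(self):
        assert annualized_change(2.0, 4.0, 2000, 2019) == pytest.approx(3.72, abs=0.005)

    def test_halving_over_31_years(self):
        assert annualized_change(4.0, 2.0, 2019, 2050) == pytest.approx(-2.21, abs=0.005)

    def test_zero_start_reported_missing(self):
        assert np.isnan(annualized_change(0.0, 4.0, 2000, 2019))


class TestProjectIncome:
    def test_listed_growth_and_world_average_fallback(self):
        income = pd.DataFrame(
            {"iso3": ["A", "B"], "year": [2021, 2021], "gni_pc": [1000.0, 2000.0]}
        )
        growth = pd.DataFrame({"iso3": ["A"], "growth_rate": [0.02]})
        out = project_income(income, growth, 2023)
        a23 = out[(out["iso3"] == "A") & (out["year"] == 2023)]["gni_pc"].iloc[0]
        b23 = out[(out["iso3"] == "B") & (out["year"] == 2023)]["gni_pc"].iloc[0]
        assert a23 == pytest.approx(1000 * 1.02**2, rel=1e-12)
        assert b23 == pytest.approx(2000 * 1.02**2, rel=1e-12)  # fallback = mean of listed

    def test_missing_base_year_rejected(self):
        income = pd.DataFrame({"iso3": ["A"], "year": [2019], "gni_pc": [1000.0]})
        with pytest.raises(ValueError, match="base year"):
            project_income(income, pd.DataFrame({"iso3": [], "growth_rate": []}), 2025)


class TestEconomicValueShare:
    def test_population_weighted_share_matches_hand_computation(self):
        """Two age groups with v/income 0.02 and 0.07 at populations
        600/400 give a 4.0% share; deltas are chosen by inverting the
        valuation at the life-table ratios the module itself reports."""
        tree = build_default_tree()
        ages = ("40-44", "60-64")
        y, year = 10_000.0, 2019
        params = ValuationParams()
        sched = pd.Series(0.01, index=list(ages))
        drl = {
            a: discounted_remaining_life(sched, m, params.discount_rate)
            for a, m in zip(ages, (42.5, 62.5))
        }
        anchor_drl = discounted_remaining_life(sched, 40.0, params.discount_rate)
        le = {a: drl[a] / anchor_drl for a in ages}
        vsl = extrapolate_vsl(y, y, params)  # region IS the anchor
        targets = {"40-44": 0.02, "60-64": 0.07}
        deltas = {a: -np.log(1 - targets[a]) * y / (vsl * le[a]) for a in ages}

        gaps = pd.DataFrame(
            {
                "region": "r",
                "sex": "female",
                "age_group": list(ages),
                "cause": "cvds",
                "year": year,
                "delta": [deltas[a] for a in ages],
            }
        )
        region_income = pd.DataFrame({"region": ["r"], "year": [year], "gni_pc": [y]})
        region_population = pd.DataFrame(
            {
                "region": "r",
                "sex": "female",
                "age_group": list(ages),
                "year": year,
                "pop": [600.0, 400.0],
            }
        )
        region_allcause = pd.DataFrame(
            {
                "region": "r",
                "sex": "female",
                "age_group": list(ages),
                "year": year,
                "rate": 0.01,
            }
        )
        anchor_income = pd.DataFrame({"year": [year], "gni_pc": [y]})
        out = economic_value_share(
            gaps, region_income, region_population, region_allcause, anchor_income, params, tree
        )
        share = out[(out["sex"] == "female") & (out["cause"] == "cvds")][
            "value_pct_income"
        ].iloc[0]
        assert share == pytest.approx(100 * (600 * 0.02 + 400 * 0.07) / 1000, rel=1e-9)
        assert share == pytest.approx(4.0, rel=1e-9)
        # single-sex world: the both-sex row equals the female row
        both = out[(out["sex"] == "both") & (out["cause"] == "cvds")][
            "value_pct_income"
        ].iloc[0]
        assert both == pytest.approx(share, rel=1e-12)

    def test_zero_gaps_give_zero_shares(self):
        tree = build_default_tree()
        gaps = pd.DataFrame(
            {
                "region": "r",
                "sex": "female",
                "age_group": ["40-44"],
                "cause": "cvds",
                "year": 2019,
                "delta": [0.0],
            }
        )
        out = economic_value_share(
            gaps,
            pd.DataFrame({"region": ["r"], "year": [2019], "gni_pc": [1000.0]}),
            pd.DataFrame(
                {"region": ["r"], "sex": ["female"], "age_group": ["40-44"], "year": [2019], "pop": [1e6]}
            ),
            pd.DataFrame(
                {"region": ["r"], "sex": ["female"], "age_group": ["40-44"], "year": [2019], "rate": [0.01]}
            ),
            pd.DataFrame({"year": [2019], "gni_pc": [50_000.0]}),
            P,
            tree,
        )
        assert (out["value_pct_income"] == 0).all()

    def test_missing_region_income_raises(self):
        tree = build_default_tree()
        gaps = pd.DataFrame(
            {
                "region": "r",
                "sex": "female",
                "age_group": ["40-44"],
                "cause": "cvds",
                "year": 2019,
                "delta": [0.001],
            }
        )
        with pytest.raises(ValueError, match="income"):
            economic_value_share(
                gaps,
                pd.DataFrame({"region": ["other"], "year": [2019], "gni_pc": [1000.0]}),
                pd.DataFrame(
                    {"region": ["r"], "sex": ["female"], "age_group": ["40-44"], "year": [2019], "pop": [1e6]}
                ),
                pd.DataFrame(
                    {"region": ["r"], "sex": ["female"], "age_group": ["40-44"], "year": [2019], "rate": [0.01]}
                ),
                pd.DataFrame({"year": [2019], "gni_pc": [50_000.0]}),
                P,
                tree,
            )
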