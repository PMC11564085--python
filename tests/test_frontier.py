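"""Frontier estimation: eligibility, percentile rule, nested rescaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evam.causes import CauseNode, CauseTree, build_default_tree
from evam.frontier import (
    EligibilityCriteria,
    check_nested_sums,
    empirical_frontier,
    nested_rescale,
    select_eligible_countries,
)
from evam.synthetic import WorldConfig, generate_world


# ---------------------------------------------------------------------------
# eligibility


@pytest.fixture(scope="module")
def world12():
    # 12 countries; 3 flagged low-VR (disjoint from the small one);
    # exactly the last country below 5M population
    return generate_world(
        WorldConfig(
            seed=21,
            n_countries=12,
            n_frontier=6,
            low_vr_indices=(5, 6, 7),
            pop_min=4.9e6,
        )
    )


class TestEligibility:
    def test_flag_enumeration(self, world12):
        w = world12
        eligible = select_eligible_countries(
            w.population, w.income, w.metadata, w.mortality
        )
        assert len(eligible) == 8  # 12 - 3 low-VR - 1 small

    def test_all_below_population_floor_raises(self, world12):
        w = world12
        crit = EligibilityCriteria(min_population=1e12)
        with pytest.raises(ValueError, match="no eligible"):
            select_eligible_countries(
                w.population, w.income, w.metadata, w.mortality, criteria=crit
            )

    def test_vacuous_criteria_admit_everyone(self, world12):
        w = world12
        crit = EligibilityCriteria(
            min_population=1.0,
            require_income=False,
            require_vr_quality=False,
            require_estimates=False,
        )
        eligible = select_eligible_countries(
            w.population, w.income, w.metadata, w.mortality, criteria=crit
        )
        assert len(eligible) == 12

    def test_min_population_must_be_positive(self):
        with pytest.raises(ValueError):
            EligibilityCriteria(min_population=0)


# ---------------------------------------------------------------------------
# empirical frontier


def _pool_frame(values, cause="stroke", sex="female"):
    return pd.DataFrame(
        {
            "sex": sex,
            "age_group": "60-64",
            "cause": cause,
            "year": 2010,
            "rate": values,
        }
    )


class TestEmpiricalFrontier:
    def test_minimum_of_pool(self):
        df = _pool_frame(np.array([2, 4, 6, 8, 10]) / 1e5)
        out = empirical_frontier(df, method="minimum")
        assert out.loc[out["sex"] == "both", "value"].iloc[0] == pytest.approx(2e-5)

    def test_p10_of_eleven_equally_spaced_is_second_order_statistic(self):
        v = np.linspace(1e-5, 11e-5, 11)
        out = empirical_frontier(_pool_frame(v), method="percentile_p10")
        # h = (n-1)p + 1 = 2 lands exactly on the 2nd order statistic
        assert out.loc[out["sex"] == "both", "value"].iloc[0] == pytest.approx(
            v[1], rel=1e-12
        )

    @given(
        st.lists(st.floats(min_value=1e-7, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=50, deadline=None)
    def test_p10_dominates_minimum(self, values):
        df = _pool_frame(values)
        p10 = empirical_frontier(df, method="percentile_p10")
        mn = empirical_frontier(df, method="minimum")
        assert (
            p10.loc[p10["sex"] == "both", "value"].iloc[0]
            >= mn.loc[mn["sex"] == "both", "value"].iloc[0]
        )

    def test_sex_specific_causes_split_and_male_zero(self):
        female = _pool_frame([1e-4, 2e-4, 3e-4], cause="breast_cancer", sex="female")
        male = _pool_frame([0.0, 0.0, 0.0], cause="breast_cancer", sex="male")
        out = empirical_frontier(pd.concat([female, male]), method="minimum")
        assert set(out["sex"]) == {"female", "male"}
        assert out.loc[out["sex"] == "male", "value"].iloc[0] == 0.0
        assert out.loc[out["sex"] == "female", "value"].iloc[0] == pytest.approx(1e-4)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            empirical_frontier(_pool_frame([1e-4]), method="median")


# ---------------------------------------------------------------------------
# nested rescaling


def toy_tree():
    return CauseTree(
        [
            CauseNode("all_causes", "All", 0),
            CauseNode("a", "A", 1, "all_causes"),
            CauseNode("b", "B", 1, "all_causes"),
            CauseNode("a1", "A1", 2, "a"),
            CauseNode("a2", "A2", 2, "a"),
        ]
    )


def frame(rows):
    return pd.DataFrame(rows, columns=["age_group", "year", "cause", "value"])


class TestNestedRescale:
    def test_level1_proportional_factor(self):
        t = CauseTree(
            [
                CauseNode("all_causes", "All", 0),
                CauseNode("x", "X", 1, "all_causes"),
                CauseNode("y", "Y", 1, "all_causes"),
                CauseNode("z", "Z", 1, "all_causes"),
            ]
        )
        df = frame(
            [
                ("a", 2000, "all_causes", 20.0),
                ("a", 2000, "x", 6.0),
                ("a", 2000, "y", 3.0),
                ("a", 2000, "z", 1.0),
            ]
        )
        out = nested_rescale(df, t).set_index("cause")["value"]
        assert out["x"] == pytest.approx(12.0)
        assert out["y"] == pytest.approx(6.0)
        assert out["z"] == pytest.approx(2.0)

    def test_already_consistent_surface_unchanged(self):
        df = frame(
            [
                ("a", 2000, "all_causes", 10.0),
                ("a", 2000, "a", 8.0),
                ("a", 2000, "b", 2.0),
                ("a", 2000, "a1", 6.0),
                ("a", 2000, "a2", 2.0),
            ]
        )
        out = nested_rescale(df, toy_tree())
        m = out.merge(df, on=["age_group", "year", "cause"], suffixes=("_new", "_old"))
        assert np.allclose(m["value_new"], m["value_old"], rtol=1e-14)

    def test_two_level_hand_computed_factors(self):
        df = frame(
            [
                ("a", 2000, "all_causes", 5.0),
                ("a", 2000, "a", 8.0),
                ("a", 2000, "b", 2.0),
                ("a", 2000, "a1", 6.0),
                ("a", 2000, "a2", 2.0),
            ]
        )
        out = nested_rescale(df, toy_tree()).set_index("cause")["value"]
        # level 1: factor 5/10 -> a=4, b=1; level 2: factor 4/8 -> a1=3, a2=1
        assert out["a"] == pytest.approx(4.0)
        assert out["b"] == pytest.approx(1.0)
        assert out["a1"] == pytest.approx(3.0)
        assert out["a2"] == pytest.approx(1.0)

    def test_zero_children_zero_target_is_noop(self):
        df = frame(
            [
                ("a", 2000, "all_causes", 0.0),
                ("a", 2000, "a", 0.0),
                ("a", 2000, "b", 0.0),
                ("a", 2000, "a1", 0.0),
                ("a", 2000, "a2", 0.0),
            ]
        )
        out = nested_rescale(df, toy_tree())
        assert (out["value"] == 0).all()

    def test_unattributable_mass_raises(self):
        df = frame(
            [
                ("a", 2000, "all_causes", 5.0),
                ("a", 2000, "a", 0.0),
                ("a", 2000, "b", 0.0),
                ("a", 2000, "a1", 0.0),
                ("a", 2000, "a2", 0.0),
            ]
        )
        with pytest.raises(ValueError, match="unattributable"):
            nested_rescale(df, toy_tree())

    def test_external_target_replaces_root(self):
        df = frame(
            [
                ("a", 2000, "all_causes", 99.0),
                ("a", 2000, "a", 8.0),
                ("a", 2000, "b", 2.0),
                ("a", 2000, "a1", 6.0),
                ("a", 2000, "a2", 2.0),
            ]
        )
        target = pd.DataFrame({"age_group": ["a"], "year": [2000], "value": [5.0]})
        out = nested_rescale(df, toy_tree(), target=target).set_index("cause")["value"]
        assert out["all_causes"] == pytest.approx(5.0)
        assert out["a"] == pytest.approx(4.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent_and_consistent_on_random_values(self, seed):
        tree = build_default_tree()
        rng = np.random.default_rng(seed)
        rows = [("a", 2000, c, float(rng.uniform(0.1, 10.0))) for c in tree.codes]
        df = frame(rows)
        once = nested_rescale(df, tree)
        assert check_nested_sums(once, tree) < 1e-9
        twice = nested_rescale(once, tree)
        m = once.merge(twice, on=["age_group", "year", "cause"], suffixes=("_1", "_2"))
        assert np.allclose(m["value_1"], m["value_2"], rtol=1e-12)


def test_pipeline_frontier_is_consistent_at_every_level(base_artifacts):
    """After level-wise rescaling, child sums equal parents everywhere on
    the observed+projected frontier surface."""
    tree = build_default_tree()
    frontier = base_artifacts["frontier"].drop(columns="provenance")
    assert check_nested_sums(frontier, tree, mixed_sex=True) < 1e-9
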