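"""Demand accounting: cohort aggregation, structures, and linearity."""

import numpy as np
import pandas as pd
import pytest

from foodgap.core_tables import FOOD_NAMES
from foodgap.demand import (
    AGE_STAGES,
    DietaryStructure,
    PopulationPyramid,
    build_demand_account,
    build_dietary_structure,
    cohort_caloric_demand,
    macronutrient_demand,
    per_capita_consumption,
    total_caloric_demand,
)
from foodgap.errors import AlignmentError
from foodgap.uma_data import guideline_bounds

from conftest import make_pyramid, make_uniform_structure


def age_resolved_structure(rng, sid="age"):
    idx = pd.MultiIndex.from_product([list(AGE_STAGES), ["all"]])
    intake = pd.DataFrame(
        rng.uniform(1e3, 2e5, (9, 9)), index=idx, columns=list(FOOD_NAMES)
    )
    return DietaryStructure(id=sid, intake=intake)


class TestCohortDemand:
    def test_zero_pyramid_gives_zero_everywhere(self, rng, factors):
        pyr = PopulationPyramid.uniform(2020, 0.0)
        out = cohort_caloric_demand(pyr, make_uniform_structure(rng), factors.calf)
        assert (out == 0).all()

    def test_single_cohort_forced_product(self):
        idx = pd.MultiIndex.from_tuples([("18-49", "female", "urban")])
        pyr = PopulationPyramid(2020, pd.Series([10.0], index=idx))
        kg = pd.Series(0.0, index=list(FOOD_NAMES))
        kg["cereals"] = 1.0  # 1000 g/person/year
        structure = DietaryStructure.uniform("t", kg)
        calf = pd.Series(2.0, index=list(FOOD_NAMES))
        out = cohort_caloric_demand(pyr, structure, calf)
        assert out["cereals"] == pytest.approx(10 * 1000 * 2)
        assert out.drop("cereals").eq(0).all()

    def test_matches_triple_loop_oracle(self, rng, factors):
        structure = age_resolved_structure(rng)
        pyr = make_pyramid(rng)
        out = cohort_caloric_demand(pyr, structure, factors.calf)
        oracle = pd.Series(0.0, index=list(FOOD_NAMES))
        for (a, s, r), pop in pyr.counts.items():
            for food in FOOD_NAMES:
                oracle[food] += pop * structure.intake.loc[(a, "all"), food]
        oracle *= factors.calf
        np.testing.assert_allclose(out, oracle, rtol=1e-9)

    def test_age_stage_mismatch_lists_missing_stages(self, rng, factors):
        partial = age_resolved_structure(rng)
        partial.intake = partial.intake.drop(index=[("80+", "all")])
        with pytest.raises(AlignmentError, match="80"):
            cohort_caloric_demand(make_pyramid(rng), partial, factors.calf)

    def test_linearity_in_population(self, rng, factors, ecf):
        structure = age_resolved_structure(rng)
        pyr = make_pyramid(rng)
        for k in (0.5, 3.0, 10.0):
            a = build_demand_account(pyr, structure, factors, ecf=ecf)
            b = build_demand_account(pyr.scaled(k), structure, factors, ecf=ecf)
            assert b.tcd == pytest.approx(k * a.tcd, rel=1e-9)
            np.testing.assert_allclose(b.mnd.to_numpy(), k * a.mnd.to_numpy(), rtol=1e-9)

    def test_parameter_recovery_closed_form(self, factors):
        # Uniform pyramid and intake: TCD_j = N × FI_j × CalF_j exactly.
        pyr = PopulationPyramid.uniform(2020, 250.0)
        n = pyr.total
        kg = pd.Series(50.0, index=list(FOOD_NAMES))
        out = cohort_caloric_demand(pyr, DietaryStructure.uniform("u", kg), factors.calf)
        np.testing.assert_allclose(out, n * 50.0 * 1e3 * factors.calf, rtol=0)


class TestTotals:
    def test_all_zeros(self):
        assert total_caloric_demand([0.0] * 9) == 0.0

    def test_wrong_cardinality(self):
        with pytest.raises(ValueError):
            total_caloric_demand([1.0] * 7)

    def test_random_batch_matches_fold_oracle(self, rng):
        for _ in range(200):
            vals = rng.uniform(0, 1e12, 9)
            acc = 0.0
            for v in vals[::-1]:
                acc += v
            assert total_caloric_demand(list(vals)) == pytest.approx(acc, rel=1e-12)


class TestMacronutrientDemand:
    def test_forced_mass(self):
        assert macronutrient_demand(1000.0, 0.6, 4.0) == pytest.approx(150.0)

    def test_zero_share(self):
        assert macronutrient_demand(5e9, 0.0, 9.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            macronutrient_demand(100.0, 0.5, 0.0)
        with pytest.raises(ValueError):
            macronutrient_demand(100.0, 1.5, 4.0)


class TestPerCapita:
    def test_forced_division(self):
        assert per_capita_consumption(1e9, 1_000_000) == pytest.approx(1.0)

    def test_zero_intake(self):
        assert per_capita_consumption(0.0, 100) == 0.0

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            per_capita_consumption(1e9, 0)

    def test_random_batch_matches_scalar_oracle(self, rng):
        for _ in range(200):
            g, pop = rng.uniform(1, 1e12), rng.uniform(1, 1e7)
            assert per_capita_consumption(g, pop) == pytest.approx(
                g / 1e3 / pop, rel=1e-12
            )


class TestStructureBuilders:
    def test_s0_mean_of_one_is_identity(self, rng):
        t = make_uniform_structure(rng, "2020")
        s0 = build_dietary_structure("S0", tables=[t])
        pd.testing.assert_frame_equal(s0.intake, t.intake)

    def test_s0_mean_of_two_forced(self, rng):
        kg = pd.Series(10.0, index=list(FOOD_NAMES))
        a = DietaryStructure.uniform("a", kg)
        b = DietaryStructure.uniform("b", kg * 2)
        s0 = build_dietary_structure("S0", tables=[a, b])
        assert (s0.intake.iloc[0] == 15.0 * 1e3).all()

    def test_s0_empty_table_set_rejected(self):
        with pytest.raises(ValueError):
            build_dietary_structure("S0", tables=[])

    def test_s1_from_guideline_upper_bounds(self):
        bounds = guideline_bounds()
        upper = DietaryStructure.uniform("upper", bounds["guideline_upper"])
        s1 = build_dietary_structure("S1", upper=upper)
        assert s1.intake_for("18-49", "urban")["cereals"] == pytest.approx(109.8e3)

    def test_s1_dominates_s2_for_published_bounds(self):
        bounds = guideline_bounds()
        s1 = build_dietary_structure(
            "S1", upper=DietaryStructure.uniform("u", bounds["guideline_upper"])
        )
        s2 = build_dietary_structure(
            "S2", lower=DietaryStructure.uniform("l", bounds["guideline_lower"])
        )
        assert s1.dominates(s2)

    def test_structure_dominance_implies_demand_dominance(self, rng, factors):
        bounds = guideline_bounds()
        s1 = DietaryStructure.uniform("S1", bounds["guideline_upper"])
        s2 = DietaryStructure.uniform("S2", bounds["guideline_lower"])
        for _ in range(20):
            pyr = make_pyramid(rng)
            d1 = total_caloric_demand(cohort_caloric_demand(pyr, s1, factors.calf))
            d2 = total_caloric_demand(cohort_caloric_demand(pyr, s2, factors.calf))
            assert d1 >= d2
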