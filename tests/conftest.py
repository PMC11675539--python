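import numpy as np
import pandas as pd
import pytest

from foodgap.core_tables import FOOD_NAMES, MacronutrientCoefficients, default_factor_table
from foodgap.demand import AGE_STAGES, DietaryStructure, PopulationPyramid, RESIDENCES, SEXES


@pytest.fixture(scope="session")
def factors():
    return default_factor_table()


@pytest.fixture(scope="session")
def ecf():
    return MacronutrientCoefficients()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def make_pyramid(rng, year=2020, scale=1e5):
    idx = pd.MultiIndex.from_product(
        [list(AGE_STAGES), list(SEXES), list(RESIDENCES)],
        names=["age_stage", "sex", "residence"],
    )
    return PopulationPyramid(year, pd.Series(rng.uniform(0, scale, len(idx)), index=idx))


def make_uniform_structure(rng, sid="S", lo=1.0, hi=200.0):
    kg = pd.Series(rng.uniform(lo, hi, 9), index=list(FOOD_NAMES))
    return DietaryStructure.uniform(sid, kg)
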