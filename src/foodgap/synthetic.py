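"""Synthetic input generator with known ground truth.

Emulates every input the pipeline consumes — paired regional/provincial
population pyramids, nine-food production series, and S0/S1/S2 intake
tables — with parameters chosen to resemble the study region: a
provincial population at the ~26 million scale, a regional share around
0.41, production levels at the magnitudes of the published 2020 accounts,
and one food (legumes) decaying toward zero to exercise the
undefined-gap path.

Ground truth is recoverable by construction: with zero noise the
regional/provincial ratio equals the configured share exactly in every
cell, trends are exact exponentials, and S1 ≥ S2 elementwise. Noise is
multiplicative log-normal (mean one), keeping all quantities positive.

Each generator draws from its own pseudo-random stream, seeded by a
stable hash of (master seed, generator name), so adding a generator never
perturbs the output of the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from foodgap.core_tables import FOOD_NAMES
from foodgap.demand import (
    AGE_STAGES,
    DietaryStructure,
    PopulationPyramid,
    RESIDENCES,
    SEXES,
)
from foodgap.production import ProductionRecord
from foodgap.uma_data import paper_fixtures  # re-exported: published-table fixtures

__all__ = [
    "GeneratorConfig",
    "gen_intake_tables",
    "gen_population_pyramid",
    "gen_production_table",
    "paper_fixtures",
    "write_synthetic_inputs",
]

#: Per-cohort base counts (provincial scale): a young-leaning pyramid
#: totalling ~26 million across 9 stages × 2 sexes × 2 residences.
_DEFAULT_BASE_COHORT = {
    "0-6": 1.30e6,
    "7-10": 0.75e6,
    "11-13": 0.55e6,
    "14-17": 0.70e6,
    "18-49": 6.50e6,
    "50-64": 1.90e6,
    "65-74": 0.75e6,
    "75-79": 0.25e6,
    "80+": 0.20e6,
}

#: Production levels (kt) at the magnitudes of the published 2020
#: accounts, with per-year trends; legumes decay steeply toward zero.
_DEFAULT_PRODUCTION = {
    "cereals": (420.0, 0.00),
    "tubers": (90.0, -0.09),
    "legumes": (10.0, -0.21),
    "vegetables": (1540.0, 0.01),
    "fruits": (25.0, 0.17),
    "meat": (140.0, 0.02),
    "eggs": (12.0, 0.04),
    "dairy": (130.0, 0.03),
    "aquatic products": (6.0, 0.03),
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic generators; defaults emulate the study region."""

    seed: int = 0
    n_years: int = 20
    start_year: int = 2001
    base_cohort: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_BASE_COHORT))
    cohort_growth: float = 0.015          # per-year exponential growth
    production_kt: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_PRODUCTION)
    )
    noise_cv: float = 0.02                # coefficient of variation, log-normal
    regional_share: float = 0.41          # regional / provincial
    s1_factor_range: tuple[float, float] = (1.3, 1.8)  # S1 = S2 × U(range)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.base_cohort.values()):
            raise ValueError("base cohort counts must be non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise scale must be non-negative")
        if not 0 <= self.regional_share <= 1:
            raise ValueError("regional share must lie in [0, 1]")


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent stream per generator: stable hash of (seed, name)."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big") % (2**31))


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1 + cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def gen_population_pyramid(
    config: GeneratorConfig,
) -> tuple[dict[int, PopulationPyramid], dict[int, PopulationPyramid]]:
    """Paired (regional, provincial) pyramid series.

    Provincial cohorts follow an exponential trend with multiplicative
    log-normal noise; the regional series is the configured share of the
    *noise-free* provincial trend, itself noised independently — so the
    share is recoverable from the pair.
    """
    rng = _stream(config.seed, "population")
    idx = pd.MultiIndex.from_product(
        [list(AGE_STAGES), list(SEXES), list(RESIDENCES)],
        names=["age_stage", "sex", "residence"],
    )
    base = pd.Series(
        [config.base_cohort.get(a, 0.0) / 4 for a, _, _ in idx], index=idx
    )
    regional, provincial = {}, {}
    for t in range(config.n_years):
        year = config.start_year + t
        clean = base * np.exp(config.cohort_growth * t)
        prov = clean * _lognormal_noise(rng, config.noise_cv, len(idx))
        reg = (
            clean
            * config.regional_share
            * _lognormal_noise(rng, config.noise_cv, len(idx))
        )
        provincial[year] = PopulationPyramid(year, prov)
        regional[year] = PopulationPyramid(year, reg)
    return regional, provincial


def gen_production_table(config: GeneratorConfig) -> dict[int, ProductionRecord]:
    """Nine-food production series with configured trends and noise."""
    rng = _stream(config.seed, "production")
    out = {}
    for t in range(config.n_years):
        year = config.start_year + t
        masses = {}
        noise = _lognormal_noise(rng, config.noise_cv, len(FOOD_NAMES))
        for i, food in enumerate(FOOD_NAMES):
            level, trend = config.production_kt[food]
            masses[food] = level * np.exp(trend * t) * noise[i]
        out[year] = ProductionRecord.from_kt(year, masses)
    return out


def gen_intake_tables(
    config: GeneratorConfig,
) -> tuple[DietaryStructure, DietaryStructure, DietaryStructure]:
    """(S0, S1, S2) uniform structures with S1 ≥ S2 by construction.

    S2 (guideline lower) is drawn first; S1 = S2 × a per-food factor ≥ 1;
    S0 (historical) is drawn between 0.5×S2 and 1.5×S1 so both deficit
    and surplus deviations occur.
    """
    rng = _stream(config.seed, "intake")
    lo, hi = config.s1_factor_range
    if lo < 1 or hi < lo:
        raise ValueError("S1 factor range must satisfy 1 <= lo <= hi")
    # kg/person/year at guideline-like magnitudes per food
    s2_base = np.array([73.2, 18.3, 5.5, 109.8, 73.2, 14.6, 14.6, 109.8, 14.6])
    s2 = s2_base * rng.uniform(0.8, 1.2, 9)
    s1 = s2 * rng.uniform(lo, hi, 9)
    s0 = rng.uniform(0.5 * s2, 1.5 * s1)
    mk = lambda sid, vals: DietaryStructure.uniform(
        sid, pd.Series(vals, index=list(FOOD_NAMES)), provenance="synthetic"
    )
    return mk("S0", s0), mk("S1", s1), mk("S2", s2)


def write_synthetic_inputs(config: GeneratorConfig, out_dir) -> list:
    """Emit the generated inputs using the pipeline's CSV schemas."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    regional, provincial = gen_population_pyramid(config)
    production = gen_production_table(config)
    s0, s1, s2 = gen_intake_tables(config)

    rows = []
    for year, rec in production.items():
        for food in FOOD_NAMES:
            rows.append({"year": year, "food": food, "mass_kt": rec.mass_g[food] / 1e9})
    pd.DataFrame(rows).to_csv(out_dir / "production.csv", index=False)

    for name, series in (("pyramid_regional", regional), ("pyramid_provincial", provincial)):
        rows = []
        for year, pyr in series.items():
            for (a, s, r), c in pyr.counts.items():
                rows.append(
                    {"year": year, "age_stage": a, "sex": s, "residence": r, "count": c}
                )
        pd.DataFrame(rows).to_csv(out_dir / f"{name}.csv", index=False)

    rows = []
    for st in (s0, s1, s2):
        for (a, r), intake in st.intake.iterrows():
            for food in FOOD_NAMES:
                rows.append(
                    {
                        "structure": st.id,
                        "age_stage": a,
                        "residence": r,
                        "food": food,
                        "kg_per_person_year": intake[food] / 1e3,
                    }
                )
    pd.DataFrame(rows).to_csv(out_dir / "intake.csv", index=False)
    return sorted(out_dir.glob("*.csv"))
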