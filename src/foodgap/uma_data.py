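"""Published Urumqi Metropolitan Area (UMA) food accounts, 2000–2020.

Transcriptions of the aggregate production and consumption accounts
published for the UMA food self-sufficiency assessment: caloric and
macronutrient production with the plant/animal partition, the nine-food
production diversity series, caloric/macronutrient demand under the
actual consumption structure and the Chinese dietary guideline bounds,
and per-capita consumption with the 2022 guideline limits. These are the
region's printed aggregates — not outputs of this package's coefficient
defaults — and serve as reference inputs for gap statistics and as
regression fixtures.

Units follow the published tables: B kcal (billion kcal) for calories,
kt (thousand tonnes) for nutrient masses and production, kg/person/year
for per-capita consumption.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

#: Caloric production (B kcal) with plant/animal partition and
#: macronutrient production (kt); quality-protein share of protein as a
#: fraction.
PRODUCTION_ACCOUNT = pd.DataFrame(
    {
        "year": [2000, 2010, 2020],
        "plant_bkcal": [2677.10, 5142.27, 3634.46],
        "animal_bkcal": [189.14, 816.00, 410.34],
        "total_bkcal": [2866.94, 5958.27, 4044.80],
        "carbohydrate_kt": [356.59, 764.07, 499.16],
        "protein_kt": [77.04, 192.72, 88.35],
        "fat_kt": [34.58, 125.33, 60.09],
        "quality_protein_share": [0.22, 0.37, 0.41],
        "provenance": ["uma-production-account"] * 3,
    }
)

#: Nine-food production (kt). Legume production in 2020 is nearly zero —
#: the canonical degenerate case for per-food gap percentages.
PRODUCTION_BY_FOOD = pd.DataFrame(
    {
        "year": [2000, 2010, 2020],
        "cereals": [465.91, 951.24, 420.17],
        "tubers": [92.23, 132.01, 13.16],
        "legumes": [10.39, 11.62, 0.2],
        "vegetables": [1362.24, 2145.04, 1538.87],
        "fruits": [22.76, 215.07, 670.54],
        "meat": [61.01, 282.05, 137.38],
        "eggs": [11.36, 32.54, 26.91],
        "dairy": [72.04, 338.25, 128.91],
        "aquatic products": [6.28, 12.75, 12.28],
        "provenance": ["uma-production-by-food"] * 3,
    }
)

#: Caloric (B kcal) and macronutrient (kt) demand under the actual
#: consumption structure and the guideline lower/upper limits.
DEMAND_ACCOUNT = pd.DataFrame(
    {
        "structure": ["actual"] * 3 + ["guideline_lower"] * 3 + ["guideline_upper"] * 3,
        "year": [2000, 2010, 2020] * 3,
        "total_bkcal": [1710.2, 2201.9, 3574.6, 1560.5, 2264.9, 2946.7, 2291.8, 3345.4, 4368.1],
        "carbohydrate_kt": [258.6, 319.2, 506.3, 224.3, 325.6, 423.6, 286.5, 418.2, 546.0],
        "protein_kt": [53.6, 72.9, 122.9, 48.8, 70.8, 92.1, 57.3, 83.6, 109.2],
        "fat_kt": [56.7, 74.4, 126.4, 34.7, 50.3, 65.5, 50.9, 74.3, 97.1],
        "provenance": ["uma-demand-account"] * 9,
    }
)

#: Per-capita consumption (kg/person/year) and the 2022 Chinese dietary
#: guideline bounds. The dairy bounds coincide (109.8 = 109.8), an
#: equal-bounds edge case preserved deliberately.
PER_CAPITA_CONSUMPTION = pd.DataFrame(
    {
        "food": [
            "cereals",
            "tubers",
            "legumes",
            "vegetables",
            "fruits",
            "meat",
            "eggs",
            "dairy",
            "aquatic products",
        ],
        "pc_2000": [128.5, 1.0, 0.5, 96.5, 64.4, 26.0, 6.4, 15.8, 3.7],
        "pc_2010": [108.5, 1.2, 0.6, 93.8, 53.4, 27.4, 7.1, 19.7, 4.7],
        "pc_2020": [128.9, 1.4, 4.7, 114.5, 69.3, 33.0, 10.7, 28.5, 10.0],
        "guideline_lower": [73.2, 18.3, 5.49, 109.8, 73.2, 14.64, 14.64, 109.8, 14.64],
        "guideline_upper": [109.8, 36.6, 9.15, 183.0, 128.1, 27.5, 18.3, 109.8, 27.5],
        "provenance": ["uma-per-capita-consumption"] * 9,
    }
)

#: Pearson correlations between the UMA and Xinjiang population
#: structures used to justify constant-share downscaling.
STRUCTURE_CORRELATIONS = pd.DataFrame(
    {
        "series": ["census-2000-2020", "SSP1-2.6", "SSP2-4.5", "SSP5-8.5"],
        "correlation_total": [0.907, 0.889, 0.999, 0.937],
        "provenance": ["uma-structure-correlation"] * 4,
    }
)

_FIXTURES = {
    "production_account.csv": PRODUCTION_ACCOUNT,
    "production_by_food.csv": PRODUCTION_BY_FOOD,
    "demand_account.csv": DEMAND_ACCOUNT,
    "per_capita_consumption.csv": PER_CAPITA_CONSUMPTION,
    "structure_correlations.csv": STRUCTURE_CORRELATIONS,
}


def paper_fixtures(out_dir: str | Path) -> list[Path]:
    """Write the published UMA accounts as pipeline-readable CSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in _FIXTURES.items():
        path = out_dir / name
        frame.to_csv(path, index=False)
        written.append(path)
    return written


def production_by_food_kt(year: int) -> pd.Series:
    """Nine-food production (kt) for one published year."""
    row = PRODUCTION_BY_FOOD[PRODUCTION_BY_FOOD["year"] == year]
    if row.empty:
        raise KeyError(f"no published production for {year}")
    return row.drop(columns=["year", "provenance"]).iloc[0].astype(float)


def per_capita_kg(year: int) -> pd.Series:
    """Per-capita consumption (kg/person/year) for one published year."""
    col = f"pc_{year}"
    if col not in PER_CAPITA_CONSUMPTION.columns:
        raise KeyError(f"no published per-capita consumption for {year}")
    return PER_CAPITA_CONSUMPTION.set_index("food")[col].astype(float)


def guideline_bounds() -> pd.DataFrame:
    """Guideline lower/upper per-capita bounds (kg/person/year) per food."""
    return PER_CAPITA_CONSUMPTION.set_index("food")[
        ["guideline_lower", "guideline_upper"]
    ].astype(float)
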