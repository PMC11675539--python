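"""Caloric and macronutrient production accounting.

Raw production mass is converted food by food into edible calories,

    TCP_j = FP_j × CF_j × CalF_j,          TCP = Σ_j TCP_j,

partitioned into plant- and animal-source subtotals, and split into
macronutrient masses using each food's energy proportions and the
Atwater-style coefficients,

    MNP_{j,q} = TCP_j × EP_{j,q} / ECF_q,  MNP_q = Σ_j MNP_{j,q}.

The division by ECF_q converts nutrient *energy* to nutrient *mass* so the
per-nutrient totals are reportable in kt alongside the B kcal calorie
totals. The share of protein mass coming from the quality-protein foods
(meat, eggs, dairy, aquatic products) is carried on the account.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from foodgap.core_tables import (
    ANIMAL_FOODS,
    FactorTable,
    MacronutrientCoefficients,
    PLANT_FOODS,
    QUALITY_PROTEIN_FOODS,
    require_nine_foods,
)


@dataclass
class ProductionRecord:
    """Raw production mass per food group for one year, in grams."""

    year: int
    mass_g: pd.Series  # indexed by food name

    def __post_init__(self) -> None:
        self.mass_g = require_nine_foods(self.mass_g, "production record")
        if (self.mass_g < 0).any():
            bad = self.mass_g[self.mass_g < 0].index.tolist()
            raise ValueError(f"negative production mass for {bad}")

    @classmethod
    def from_kt(cls, year: int, mass_kt: Mapping[str, float] | pd.Series) -> "ProductionRecord":
        s = pd.Series(dict(mass_kt)) if not isinstance(mass_kt, pd.Series) else mass_kt
        return cls(year=year, mass_g=s * 1e9)


@dataclass
class ProductionAccount:
    """Caloric and macronutrient production for one year.

    Energies in kcal, nutrient masses in g (canonical units); the
    reporting layer converts to B kcal / kt.
    """

    year: int
    tcp_j: pd.Series          # kcal per food
    tcp: float                # kcal
    plant_tcp: float
    animal_tcp: float
    mnp: pd.DataFrame         # g, food × nutrient
    mnp_q: pd.Series          # g per nutrient
    quality_protein_share: float

    def source_subtotal(self, source_class: str) -> float:
        if source_class == "plant":
            return self.plant_tcp
        if source_class == "animal":
            return self.animal_tcp
        raise ValueError(f"unknown source class {source_class!r}")


def food_caloric_production(fp_g: float, cf: float, calf: float) -> float:
    """Caloric production of one food: FP_j × CF_j × CalF_j (kcal)."""
    if fp_g < 0 or cf < 0 or calf < 0:
        raise ValueError("production inputs must be non-negative")
    return fp_g * cf * calf


def total_caloric_production(
    tcp_j: pd.Series | Iterable[float],
) -> tuple[float, float, float]:
    """Total caloric production with plant/animal partition.

    Returns ``(tcp, plant_tcp, animal_tcp)``; input must cover all nine
    foods (by name, or positionally in canonical order).
    """
    s = require_nine_foods(tcp_j, "per-food calories")
    if (s < 0).any():
        raise ValueError("per-food calories must be non-negative")
    plant = float(s[list(PLANT_FOODS & set(s.index))].sum())
    animal = float(s[list(ANIMAL_FOODS & set(s.index))].sum())
    return float(s.sum()), plant, animal


def macronutrient_production(tcp_j: float, ep: float, ecf: float) -> float:
    """Nutrient mass produced by one food: TCP_j × EP_{j,q} / ECF_q (g)."""
    if tcp_j < 0 or ep < 0:
        raise ValueError("inputs must be non-negative")
    if ecf <= 0:
        raise ValueError("energy-conversion coefficient must be positive")
    return tcp_j * ep / ecf


def quality_protein_share(
    protein_g: pd.Series | Iterable[float],
    flags: Iterable[bool] | None = None,
) -> float:
    """Fraction of total protein mass from quality-protein foods.

    With no explicit ``flags``, the canonical meat/eggs/dairy/aquatic set
    is used. Raises :class:`ValueError` when total protein is zero.
    """
    s = require_nine_foods(protein_g, "protein masses")
    if (s < 0).any():
        raise ValueError("protein masses must be non-negative")
    total = float(s.sum())
    if total == 0:
        raise ValueError("quality-protein share undefined: total protein is zero")
    if flags is None:
        flagged = float(s[list(QUALITY_PROTEIN_FOODS & set(s.index))].sum())
    else:
        mask = np.asarray(list(flags), dtype=bool)
        if mask.shape != (9,):
            raise ValueError("flags must have nine entries")
        flagged = float(s.to_numpy()[mask].sum())
    return flagged / total


def build_production_account(
    record: ProductionRecord,
    factors: FactorTable,
    ecf: MacronutrientCoefficients | None = None,
) -> ProductionAccount:
    """Run the full production accounting for one year's record."""
    ecf = ecf or MacronutrientCoefficients()
    tcp_j = record.mass_g * factors.cf * factors.calf
    tcp, plant, animal = total_caloric_production(tcp_j)
    mnp = factors.ep_matrix.mul(tcp_j, axis=0) / ecf.as_series()
    mnp_q = mnp.sum(axis=0)
    share = (
        quality_protein_share(mnp["protein"]) if mnp_q["protein"] > 0 else float("nan")
    )
    return ProductionAccount(
        year=record.year,
        tcp_j=tcp_j,
        tcp=tcp,
        plant_tcp=plant,
        animal_tcp=animal,
        mnp=mnp,
        mnp_q=mnp_q,
        quality_protein_share=share,
    )


def read_production_csv(path) -> dict[int, ProductionRecord]:
    """Read ``production.csv`` (year, food, mass_kt) into per-year records."""
    from foodgap.errors import SchemaError

    df = pd.read_csv(path)
    needed = {"year", "food", "mass_kt"}
    if not needed <= set(df.columns):
        raise SchemaError(f"production table needs columns {sorted(needed)}")
    if df.empty:
        raise SchemaError(f"production table {path} has no rows")
    records = {}
    for year, sub in df.groupby("year"):
        records[int(year)] = ProductionRecord.from_kt(
            int(year), sub.set_index("food")["mass_kt"]
        )
    return records


def account_frame(accounts: Iterable[ProductionAccount]) -> pd.DataFrame:
    """Tabulate accounts in reporting units (B kcal, kt), one row per year."""
    rows = []
    for a in accounts:
        rows.append(
            {
                "year": a.year,
                "plant_bkcal": a.plant_tcp / 1e9,
                "animal_bkcal": a.animal_tcp / 1e9,
                "total_bkcal": a.tcp / 1e9,
                "carbohydrate_kt": a.mnp_q["carbohydrate"] / 1e9,
                "protein_kt": a.mnp_q["protein"] / 1e9,
                "fat_kt": a.mnp_q["fat"] / 1e9,
                "quality_protein_share": a.quality_protein_share,
            }
        )
    return pd.DataFrame(rows)
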