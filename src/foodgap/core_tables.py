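"""Domain vocabulary, unit registry, and validated factor tables.

The balance sheet covers nine food groups. Four of them — meat, eggs,
dairy, and aquatic products — are animal-source foods and also the
high-quality-protein foods (complete essential amino acid profile); the
other five are plant-source.

Factor tables hold, per food group *j*:

* ``cf`` — edible-conversion factor CF_j (raw mass → edible mass, fraction),
* ``calf`` — caloric factor CalF_j (kcal per g edible mass),
* ``ep_carb``/``ep_protein``/``ep_fat`` — the fraction of food *j*'s energy
  contributed by each macronutrient *q* (EP_{j,q}).

Atwater-style energy-conversion coefficients ECF_q (kcal per g of nutrient)
convert nutrient energy into nutrient mass; defaults are 4/4/9 for
carbohydrate/protein/fat.

All internal computation is in canonical units (g, kcal). Reporting uses
kt (1 kt = 1e9 g) and B kcal (billion kcal, 1e9 kcal).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from foodgap.errors import SchemaError, UnitError

NUTRIENTS = ("carbohydrate", "protein", "fat")

EP_COLUMNS = {"carbohydrate": "ep_carb", "protein": "ep_protein", "fat": "ep_fat"}


@dataclass(frozen=True)
class FoodGroup:
    """One of the nine food groups of the balance sheet."""

    index: int
    name: str
    source_class: str  # "plant" | "animal"
    quality_protein: bool


FOOD_GROUPS: tuple[FoodGroup, ...] = (
    FoodGroup(1, "cereals", "plant", False),
    FoodGroup(2, "tubers", "plant", False),
    FoodGroup(3, "legumes", "plant", False),
    FoodGroup(4, "vegetables", "plant", False),
    FoodGroup(5, "fruits", "plant", False),
    FoodGroup(6, "meat", "animal", True),
    FoodGroup(7, "eggs", "animal", True),
    FoodGroup(8, "dairy", "animal", True),
    FoodGroup(9, "aquatic products", "animal", True),
)

FOOD_NAMES: tuple[str, ...] = tuple(g.name for g in FOOD_GROUPS)
ANIMAL_FOODS: frozenset[str] = frozenset(g.name for g in FOOD_GROUPS if g.source_class == "animal")
PLANT_FOODS: frozenset[str] = frozenset(g.name for g in FOOD_GROUPS if g.source_class == "plant")
QUALITY_PROTEIN_FOODS: frozenset[str] = frozenset(
    g.name for g in FOOD_GROUPS if g.quality_protein
)


# ---------------------------------------------------------------------------
# Unit registry
# ---------------------------------------------------------------------------

#: unit -> (dimension, factor to the canonical unit of that dimension)
_UNITS: dict[str, tuple[str, float]] = {
    "g": ("mass", 1.0),
    "kg": ("mass", 1e3),
    "t": ("mass", 1e6),
    "kt": ("mass", 1e9),
    "kcal": ("energy", 1.0),
    "bkcal": ("energy", 1e9),
    "person": ("count", 1.0),
}


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between registered units of the same dimension.

    Raises :class:`UnitError` for unknown units or a dimension mismatch
    (e.g. kt → kcal).
    """
    try:
        dim_from, f_from = _UNITS[from_unit]
    except KeyError:
        raise UnitError(f"unknown unit {from_unit!r}") from None
    try:
        dim_to, f_to = _UNITS[to_unit]
    except KeyError:
        raise UnitError(f"unknown unit {to_unit!r}") from None
    if dim_from != dim_to:
        raise UnitError(
            f"cannot convert {from_unit!r} ({dim_from}) to {to_unit!r} ({dim_to})"
        )
    return value * (f_from / f_to)


# ---------------------------------------------------------------------------
# Factor tables
# ---------------------------------------------------------------------------


@dataclass
class FactorTable:
    """Edible-conversion, caloric, and macronutrient-energy factors per food.

    ``data`` is indexed by food name with columns
    ``cf, calf, ep_carb, ep_protein, ep_fat``; ``provenance`` records where
    the coefficients came from.
    """

    data: pd.DataFrame
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        required = ["cf", "calf", "ep_carb", "ep_protein", "ep_fat"]
        missing_cols = [c for c in required if c not in self.data.columns]
        if missing_cols:
            raise SchemaError(f"factor table missing columns: {missing_cols}")
        missing = [n for n in FOOD_NAMES if n not in self.data.index]
        if missing:
            raise SchemaError(f"factor table missing food groups: {missing}")
        extra = [n for n in self.data.index if n not in FOOD_NAMES]
        if extra:
            raise SchemaError(f"factor table has unknown food groups: {extra}")
        self.data = self.data.loc[list(FOOD_NAMES), required].astype(float)
        for food, row in self.data.iterrows():
            if not 0 < row["cf"] <= 1.5:
                raise ValueError(f"{food}/cf out of range (0, 1.5]: {row['cf']}")
            if row["calf"] <= 0:
                raise ValueError(f"{food}/calf must be positive: {row['calf']}")
            for col in ("ep_carb", "ep_protein", "ep_fat"):
                if not 0 <= row[col] <= 1:
                    raise ValueError(f"{food}/{col} out of range [0, 1]: {row[col]}")

    @property
    def cf(self) -> pd.Series:
        return self.data["cf"]

    @property
    def calf(self) -> pd.Series:
        return self.data["calf"]

    def ep(self, nutrient: str) -> pd.Series:
        """Energy proportion of ``nutrient`` across foods."""
        return self.data[EP_COLUMNS[nutrient]]

    @property
    def ep_matrix(self) -> pd.DataFrame:
        """Food × nutrient energy-proportion matrix."""
        m = self.data[[EP_COLUMNS[q] for q in NUTRIENTS]].copy()
        m.columns = list(NUTRIENTS)
        return m

    def to_csv(self, path: str | Path) -> None:
        out = self.data.reset_index().rename(columns={"index": "food"})
        out.to_csv(path, index=False)

    def equals(self, other: "FactorTable", tol: float = 1e-12) -> bool:
        return bool(((self.data - other.data).abs() <= tol).all().all())


def load_factor_table(path: str | Path, provenance: str | None = None) -> FactorTable:
    """Read ``factors.csv`` (food, cf, calf, ep_carb, ep_protein, ep_fat)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if "food" not in df.columns:
        raise SchemaError("factor table must have a 'food' column")
    df = df.set_index("food")
    return FactorTable(df, provenance=provenance or str(path))


def validate_energy_proportions(table: FactorTable) -> list[str]:
    """Warn for foods whose macronutrient energy shares do not sum near 1.

    The shares may legitimately sum slightly below 1 (fibre, organic acids,
    alcohol); sums below 0.9 or above 1 are suspicious and returned as
    warning strings. An empty list means all foods pass.
    """
    warnings = []
    sums = table.ep_matrix.sum(axis=1)
    for food, s in sums.items():
        if s < 0.9:
            warnings.append(f"{food}: macronutrient energy shares sum to {s:.3f} < 0.9")
        elif s > 1 + 1e-6:
            warnings.append(f"{food}: macronutrient energy shares sum to {s:.3f} > 1")
    return warnings


@dataclass(frozen=True)
class MacronutrientCoefficients:
    """Atwater-style energy-conversion coefficients, kcal per g of nutrient."""

    carbohydrate: float = 4.0
    protein: float = 4.0
    fat: float = 9.0

    def __post_init__(self) -> None:
        for q in NUTRIENTS:
            if getattr(self, q) <= 0:
                raise ValueError(f"ECF for {q} must be positive")

    def __getitem__(self, nutrient: str) -> float:
        if nutrient not in NUTRIENTS:
            raise KeyError(nutrient)
        return getattr(self, nutrient)

    def as_series(self) -> pd.Series:
        return pd.Series({q: getattr(self, q) for q in NUTRIENTS})


def load_ecf(path: str | Path) -> MacronutrientCoefficients:
    """Read ``ecf.csv`` (nutrient, kcal_per_g)."""
    df = pd.read_csv(path)
    if not {"nutrient", "kcal_per_g"} <= set(df.columns):
        raise SchemaError("ecf table needs columns: nutrient, kcal_per_g")
    vals = df.set_index("nutrient")["kcal_per_g"]
    missing = [q for q in NUTRIENTS if q not in vals.index]
    if missing:
        raise SchemaError(f"ecf table missing nutrients: {missing}")
    return MacronutrientCoefficients(**{q: float(vals[q]) for q in NUTRIENTS})


# Default per-food coefficients assembled from conventional Chinese
# food-composition values (edible fractions, energy densities, and
# macronutrient energy splits typical of each group's dominant items).
# They are deliberately round, clearly labelled defaults: any analysis that
# must match published aggregate accounts should consume those accounts
# directly rather than rederive them from these coefficients.
_DEFAULT_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    # food: (cf, calf kcal/g, ep_carb, ep_protein, ep_fat)
    "cereals": (0.85, 3.47, 0.78, 0.11, 0.08),
    "tubers": (0.90, 0.81, 0.89, 0.08, 0.02),
    "legumes": (1.00, 3.81, 0.36, 0.35, 0.28),
    "vegetables": (0.85, 0.26, 0.68, 0.21, 0.09),
    "fruits": (0.80, 0.52, 0.90, 0.05, 0.04),
    "meat": (0.75, 2.51, 0.02, 0.28, 0.70),
    "eggs": (0.88, 1.44, 0.03, 0.33, 0.64),
    "dairy": (1.00, 0.65, 0.33, 0.19, 0.47),
    "aquatic products": (0.60, 1.08, 0.04, 0.74, 0.21),
}


def default_factor_table() -> FactorTable:
    """Default factor table (clearly marked; not a published reproduction)."""
    df = pd.DataFrame.from_dict(
        _DEFAULT_FACTORS,
        orient="index",
        columns=["cf", "calf", "ep_carb", "ep_protein", "ep_fat"],
    )
    return FactorTable(df, provenance="default")


def require_nine_foods(values: pd.Series | Iterable[float], what: str) -> pd.Series:
    """Coerce to a Series indexed by the nine food names, enforcing coverage."""
    if isinstance(values, pd.Series):
        missing = [n for n in FOOD_NAMES if n not in values.index]
        if missing:
            raise SchemaError(f"{what} missing food groups: {missing}")
        return values.loc[list(FOOD_NAMES)].astype(float)
    vals = list(values)
    if len(vals) != 9:
        raise ValueError(f"{what} must have exactly nine entries, got {len(vals)}")
    return pd.Series(vals, index=list(FOOD_NAMES), dtype=float)
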