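"""Caloric and macronutrient demand from population and dietary structure.

Demand aggregates per-capita intake over a cohort-structured population,

    TCD_j = Σ_a Pop_a × FI_{a,j} × CalF_j,     TCD = Σ_j TCD_j,

where *a* runs over nine age stages (each possibly split by sex and
urban/rural residence) and FI_{a,j} is the per-capita intake of food *j*
in grams per person per year. Macronutrient demand converts each food's
caloric demand into nutrient mass with the same energy-share /
Atwater-coefficient scheme used on the production side:

    MND_{q,j} = TCD_j × NRGP_{q,j} / ECF_q.

Dietary structures come in three flavours: S0, the historical (actual)
consumption structure, optionally distinct for urban and rural residents;
S1, the guideline upper consumption limits; S2, the guideline lower
limits. S1/S2 are residence-invariant. A structure may be *uniform*
(age-invariant per-capita intake, as published per-capita consumption
tables are) or age-resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from foodgap.core_tables import (
    FOOD_NAMES,
    FactorTable,
    MacronutrientCoefficients,
    NUTRIENTS,
    require_nine_foods,
)
from foodgap.errors import AlignmentError, SchemaError

#: Default nine age stages (guideline-style bands). Configurable: any list
#: of nine labels shared between pyramid and structure works.
AGE_STAGES: tuple[str, ...] = (
    "0-6",
    "7-10",
    "11-13",
    "14-17",
    "18-49",
    "50-64",
    "65-74",
    "75-79",
    "80+",
)

SEXES = ("female", "male")
RESIDENCES = ("urban", "rural")


@dataclass
class PopulationPyramid:
    """Cohort counts by age stage × sex × residence for one year.

    ``counts`` is a Series with a (age_stage, sex, residence) MultiIndex.
    Missing cells are treated as zero on access, but the constructor
    requires non-negative counts.
    """

    year: int
    counts: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.counts.index, pd.MultiIndex) or self.counts.index.nlevels != 3:
            raise SchemaError(
                "pyramid counts need a (age_stage, sex, residence) MultiIndex"
            )
        self.counts = self.counts.astype(float)
        self.counts.index = self.counts.index.set_names(["age_stage", "sex", "residence"])
        if (self.counts < 0).any():
            raise ValueError("population counts must be non-negative")

    @property
    def age_stages(self) -> list[str]:
        return sorted(set(self.counts.index.get_level_values("age_stage")))

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def by_age_residence(self) -> pd.Series:
        """Counts aggregated over sex, indexed by (age_stage, residence)."""
        return self.counts.groupby(level=["age_stage", "residence"]).sum()

    def scaled(self, k: float) -> "PopulationPyramid":
        return PopulationPyramid(self.year, self.counts * k)

    @classmethod
    def uniform(
        cls,
        year: int,
        count_per_cell: float,
        age_stages: Sequence[str] = AGE_STAGES,
    ) -> "PopulationPyramid":
        idx = pd.MultiIndex.from_product(
            [list(age_stages), list(SEXES), list(RESIDENCES)],
            names=["age_stage", "sex", "residence"],
        )
        return cls(year, pd.Series(count_per_cell, index=idx, dtype=float))


@dataclass
class DietaryStructure:
    """Per-capita intake FI_{a,j} in g/person/year.

    ``intake`` is a DataFrame indexed by (age_stage, residence) — either
    level may use the wildcard ``"all"`` — with one column per food group.
    ``build_dietary_structure`` and :meth:`uniform` are the usual
    constructors.
    """

    id: str
    intake: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.intake.index, pd.MultiIndex) or self.intake.index.nlevels != 2:
            raise SchemaError("intake needs a (age_stage, residence) MultiIndex")
        self.intake.index = self.intake.index.set_names(["age_stage", "residence"])
        missing = [f for f in FOOD_NAMES if f not in self.intake.columns]
        if missing:
            raise SchemaError(f"dietary structure missing foods: {missing}")
        self.intake = self.intake[list(FOOD_NAMES)].astype(float)
        if (self.intake < 0).any().any():
            raise ValueError("per-capita intake must be non-negative")

    @classmethod
    def uniform(
        cls,
        id: str,
        kg_per_person_year: Mapping[str, float] | pd.Series,
        provenance: str = "",
    ) -> "DietaryStructure":
        """Age- and residence-invariant structure from kg/person/year."""
        s = require_nine_foods(pd.Series(dict(kg_per_person_year)), f"structure {id}")
        df = pd.DataFrame(
            [s * 1e3],
            index=pd.MultiIndex.from_tuples([("all", "all")]),
        )
        return cls(id=id, intake=df, provenance=provenance)

    def intake_for(self, age_stage: str, residence: str) -> pd.Series:
        """FI_{a,j} for a cohort, resolving ``"all"`` wildcards (g/person/yr)."""
        for key in (
            (age_stage, residence),
            (age_stage, "all"),
            ("all", residence),
            ("all", "all"),
        ):
            if key in self.intake.index:
                return self.intake.loc[key]
        raise AlignmentError(
            f"structure {self.id!r} has no intake for age stage {age_stage!r}, "
            f"residence {residence!r}"
        )

    def covers(self, age_stages: Iterable[str]) -> list[str]:
        """Age stages *not* covered by this structure (empty when aligned)."""
        have = set(self.intake.index.get_level_values("age_stage"))
        if "all" in have:
            return []
        return [a for a in age_stages if a not in have]

    def dominates(self, other: "DietaryStructure") -> bool:
        """True if this structure's intake ≥ ``other``'s elementwise."""
        if list(self.intake.index) != list(other.intake.index):
            return False
        return bool((self.intake.to_numpy() >= other.intake.to_numpy() - 1e-12).all())


@dataclass
class DemandAccount:
    """Caloric and macronutrient demand for one population/structure pair."""

    year: int | None
    structure_id: str
    tcd_j: pd.Series        # kcal per food
    tcd: float              # kcal
    mnd: pd.DataFrame       # g, food × nutrient
    mnd_q: pd.Series        # g per nutrient
    tags: dict = field(default_factory=dict)


def cohort_caloric_demand(
    pyramid: PopulationPyramid,
    structure: DietaryStructure,
    calf: pd.Series,
) -> pd.Series:
    """Per-food caloric demand TCD_j = Σ_a Pop_a × FI_{a,j} × CalF_j (kcal)."""
    calf = require_nine_foods(calf, "caloric factors")
    if (calf <= 0).any():
        raise ValueError("caloric factors must be positive")
    missing = structure.covers(pyramid.age_stages)
    if missing:
        raise AlignmentError(f"structure {structure.id!r} missing age stages: {missing}")
    total_intake = pd.Series(0.0, index=list(FOOD_NAMES))
    for (age, res), pop in pyramid.by_age_residence().items():
        if pop == 0:
            continue
        total_intake = total_intake + pop * structure.intake_for(age, res)
    return total_intake * calf


def total_caloric_demand(tcd_j: pd.Series | Iterable[float]) -> float:
    """TCD = Σ_j TCD_j over the nine foods (kcal)."""
    s = require_nine_foods(tcd_j, "per-food demand")
    if (s < 0).any():
        raise ValueError("per-food demand must be non-negative")
    return float(s.sum())


def macronutrient_demand(tcd_j: float, nrgp: float, ecf: float) -> float:
    """Nutrient mass demanded through one food: TCD_j × NRGP_{q,j} / ECF_q (g)."""
    if tcd_j < 0 or nrgp < 0 or nrgp > 1:
        raise ValueError("demand must be non-negative and share in [0, 1]")
    if ecf <= 0:
        raise ValueError("energy-conversion coefficient must be positive")
    return tcd_j * nrgp / ecf


def per_capita_consumption(total_g: float, population: float) -> float:
    """Total intake mass over population, in kg/person/year."""
    if population <= 0:
        raise ValueError("population must be positive")
    if total_g < 0:
        raise ValueError("intake mass must be non-negative")
    return total_g / 1e3 / population


def build_dietary_structure(
    mode: str,
    tables: Sequence[DietaryStructure] | None = None,
    upper: DietaryStructure | None = None,
    lower: DietaryStructure | None = None,
) -> DietaryStructure:
    """Assemble S0/S1/S2 structures.

    S0 is the arithmetic mean of the supplied historical intake tables
    (per food, and per (age, residence) cell when they are resolved);
    S1 adopts the guideline upper bounds; S2 the lower bounds.
    """
    if mode == "S0":
        if not tables:
            raise ValueError("S0 requires at least one historical intake table")
        idx = tables[0].intake.index
        for t in tables[1:]:
            if list(t.intake.index) != list(idx):
                raise AlignmentError("historical tables must share the same cells")
        mean = sum(t.intake for t in tables) / len(tables)
        prov = "mean of " + ", ".join(t.id for t in tables)
        return DietaryStructure(id="S0", intake=mean, provenance=prov)
    if mode == "S1":
        if upper is None:
            raise ValueError("S1 requires the guideline upper-bound table")
        return DietaryStructure(id="S1", intake=upper.intake.copy(), provenance="guideline upper limit")
    if mode == "S2":
        if lower is None:
            raise ValueError("S2 requires the guideline lower-bound table")
        return DietaryStructure(id="S2", intake=lower.intake.copy(), provenance="guideline lower limit")
    raise ValueError(f"unknown structure mode {mode!r}")


def build_demand_account(
    pyramid: PopulationPyramid,
    structure: DietaryStructure,
    factors: FactorTable,
    ecf: MacronutrientCoefficients | None = None,
    nrgp: pd.DataFrame | None = None,
    tags: dict | None = None,
) -> DemandAccount:
    """Full demand accounting for one pyramid/structure pair.

    ``nrgp`` (food × nutrient energy ratios) defaults to the factor
    table's production-side energy proportions.
    """
    ecf = ecf or MacronutrientCoefficients()
    tcd_j = cohort_caloric_demand(pyramid, structure, factors.calf)
    tcd = total_caloric_demand(tcd_j)
    shares = nrgp if nrgp is not None else factors.ep_matrix
    shares = shares.loc[list(FOOD_NAMES), list(NUTRIENTS)]
    mnd = shares.mul(tcd_j, axis=0) / ecf.as_series()
    return DemandAccount(
        year=pyramid.year,
        structure_id=structure.id,
        tcd_j=tcd_j,
        tcd=tcd,
        mnd=mnd,
        mnd_q=mnd.sum(axis=0),
        tags=dict(tags or {}),
    )


def read_pyramid_csv(path) -> dict[int, PopulationPyramid]:
    """Read ``pyramid.csv`` (year, age_stage, sex, residence, count)."""
    df = pd.read_csv(path)
    needed = {"year", "age_stage", "sex", "residence", "count"}
    if not needed <= set(df.columns):
        raise SchemaError(f"pyramid table needs columns {sorted(needed)}")
    out = {}
    for year, sub in df.groupby("year"):
        counts = sub.set_index(["age_stage", "sex", "residence"])["count"]
        out[int(year)] = PopulationPyramid(int(year), counts)
    return out


def read_intake_csv(path) -> dict[str, DietaryStructure]:
    """Read ``intake.csv`` (structure, age_stage, residence, food, kg_per_person_year)."""
    df = pd.read_csv(path)
    needed = {"structure", "age_stage", "residence", "food", "kg_per_person_year"}
    if not needed <= set(df.columns):
        raise SchemaError(f"intake table needs columns {sorted(needed)}")
    out = {}
    for sid, sub in df.groupby("structure"):
        wide = sub.pivot_table(
            index=["age_stage", "residence"],
            columns="food",
            values="kg_per_person_year",
        )
        out[str(sid)] = DietaryStructure(id=str(sid), intake=wide * 1e3)
    return out
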