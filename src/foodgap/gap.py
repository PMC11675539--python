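"""Self-sufficiency gap statistics and dietary-deviation measures.

The production-demand gap is the signed percentage

    Gap = (demand − production) / production × 100,

computed at three resolutions: total calories, per macronutrient, and per
food group. Gap ≤ 0 means local production meets demand ("met"); Gap > 0
means a deficit covered only by external supply. When production is zero
(or below a configurable floor) while demand is positive the percentage is
undefined; batch reports flag such entries and carry the absolute
shortfall instead of a percentage.

Guideline deviations compare per-capita consumption with a guideline
bound. Published deviation percentages use two denominators
interchangeably, so the convention is an explicit parameter and every
report names it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from foodgap.core_tables import FOOD_NAMES, NUTRIENTS
from foodgap.demand import DemandAccount
from foodgap.errors import UndefinedGapError
from foodgap.production import ProductionAccount


@dataclass
class GapReport:
    """Gap table at total / nutrient / food resolution.

    ``table`` columns: level, item, demand, production, gap_pct, flag,
    shortfall. ``flag`` ∈ {met, deficit, undefined}; ``gap_pct`` is NaN for
    undefined entries (the absolute shortfall is retained). Values are in
    canonical units (kcal for the total row, g for nutrient/food rows).
    """

    table: pd.DataFrame
    convention: str = "gap = (demand - production) / production * 100"

    def row(self, level: str, item: str) -> pd.Series:
        m = self.table[(self.table["level"] == level) & (self.table["item"] == item)]
        if m.empty:
            raise KeyError((level, item))
        return m.iloc[0]

    @property
    def gap_total(self) -> float:
        return float(self.row("total", "calories")["gap_pct"])

    def gap_nutrient(self, nutrient: str) -> float:
        return float(self.row("nutrient", nutrient)["gap_pct"])

    def gap_food(self, food: str) -> float:
        return float(self.row("food", food)["gap_pct"])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["convention"] = self.convention
        out.to_csv(path, index=False)


def gap_percent(demand: float, production: float) -> float:
    """Signed gap percentage; raises :class:`UndefinedGapError` at zero production."""
    if demand < 0 or production < 0:
        raise ValueError("demand and production must be non-negative")
    if production == 0:
        if demand == 0:
            return 0.0
        raise UndefinedGapError("gap undefined: zero production with positive demand")
    return (demand - production) / production * 100.0


def _flag(demand: float, production: float, floor: float) -> str:
    if production <= floor and demand > production:
        return "undefined"
    return "met" if demand <= production else "deficit"


def per_food_gap(
    demand_j: pd.Series | Iterable[float],
    production_j: pd.Series | Iterable[float],
    floor: float = 0.0,
) -> pd.DataFrame:
    """Per-food gap table with the undefined-flag path for zero production.

    ``floor`` is the production level (same units as the inputs) below
    which a percentage is deemed meaningless and flagged instead.
    """
    d = pd.Series(list(demand_j), index=list(FOOD_NAMES), dtype=float) \
        if not isinstance(demand_j, pd.Series) else demand_j.astype(float)
    p = pd.Series(list(production_j), index=list(FOOD_NAMES), dtype=float) \
        if not isinstance(production_j, pd.Series) else production_j.astype(float)
    rows = []
    for food in FOOD_NAMES:
        dv, pv = float(d[food]), float(p[food])
        flag = _flag(dv, pv, floor)
        gap = np.nan if flag == "undefined" else gap_percent(dv, pv)
        rows.append(
            {
                "level": "food",
                "item": food,
                "demand": dv,
                "production": pv,
                "gap_pct": gap,
                "flag": flag,
                "shortfall": max(dv - pv, 0.0),
            }
        )
    return pd.DataFrame(rows)


def gap_report(
    demand: DemandAccount,
    production: ProductionAccount,
    floor: float = 0.0,
) -> GapReport:
    """Assemble the full three-resolution gap report for one year."""
    rows = [
        {
            "level": "total",
            "item": "calories",
            "demand": demand.tcd,
            "production": production.tcp,
            "gap_pct": np.nan
            if _flag(demand.tcd, production.tcp, floor) == "undefined"
            else gap_percent(demand.tcd, production.tcp),
            "flag": _flag(demand.tcd, production.tcp, floor),
            "shortfall": max(demand.tcd - production.tcp, 0.0),
        }
    ]
    for q in NUTRIENTS:
        dv, pv = float(demand.mnd_q[q]), float(production.mnp_q[q])
        flag = _flag(dv, pv, floor)
        rows.append(
            {
                "level": "nutrient",
                "item": q,
                "demand": dv,
                "production": pv,
                "gap_pct": np.nan if flag == "undefined" else gap_percent(dv, pv),
                "flag": flag,
                "shortfall": max(dv - pv, 0.0),
            }
        )
    table = pd.concat(
        [pd.DataFrame(rows), per_food_gap(demand.tcd_j, production.tcp_j, floor)],
        ignore_index=True,
    )
    return GapReport(table=table)


def guideline_deviation(
    consumption: float,
    bound: float,
    denominator: str = "guideline",
    direction: str = "below",
) -> float:
    """Percent deviation of consumption from a guideline bound.

    ``direction="below"`` measures shortfall against a lower bound:
    (bound − consumption) / denom × 100, positive when consumption is below
    the bound. ``direction="above"`` measures excess over an upper bound:
    (consumption − bound) / denom × 100, positive when consumption exceeds
    it. ``denominator`` chooses the reference: the guideline bound or the
    consumption itself (both conventions appear in published accounts).
    """
    if consumption < 0 or bound < 0:
        raise ValueError("consumption and bound must be non-negative")
    denom = {"guideline": bound, "consumption": consumption}.get(denominator)
    if denom is None:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    if denom == 0:
        raise ValueError("deviation denominator is zero")
    if direction == "below":
        return (bound - consumption) / denom * 100.0
    if direction == "above":
        return (consumption - bound) / denom * 100.0
    raise ValueError(f"unknown direction {direction!r}")


def production_trend_ratio(value_t: float, value_0: float, mode: str = "fold") -> float:
    """Trend of a series endpoint against its baseline.

    ``fold`` returns value_t / value_0 (e.g. "29 times the 2000 output");
    ``percent-of-baseline`` returns the same × 100 (e.g. "14.2% of the 2000
    production").
    """
    if value_0 <= 0:
        raise ValueError("baseline value must be positive")
    if value_t < 0:
        raise ValueError("current value must be non-negative")
    ratio = value_t / value_0
    if mode == "fold":
        return ratio
    if mode == "percent-of-baseline":
        return ratio * 100.0
    raise ValueError(f"unknown mode {mode!r}")


def source_class_share(account: ProductionAccount, source_class: str) -> float:
    """Percent of total caloric production from plant- or animal-source foods."""
    if account.tcp <= 0:
        raise ValueError("total caloric production must be positive")
    return account.source_subtotal(source_class) / account.tcp * 100.0
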