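"""Scenario demand projection from downscaled cohort trajectories.

Provincial cohort projections under coupled SSP-RCP scenarios are
downscaled to the study region with a constant per-cohort share model:
the regional-to-provincial ratio is averaged over the overlapping
observed years (census years, typically), justified by the high Pearson
correlation between the two population structures. Annual regional
pyramids are then averaged over three fixed term windows — basic
2011–2030, near 2021–2040, mid 2041–2060 — and each term pyramid is fed
through the demand module under a chosen dietary structure. Future gaps
compare projected demand against a frozen baseline-year production
account (2020 by default), i.e. they isolate demand-side pressure under
an unchanged production capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from foodgap.core_tables import FactorTable, MacronutrientCoefficients
from foodgap.demand import (
    DemandAccount,
    DietaryStructure,
    PopulationPyramid,
    build_demand_account,
)
from foodgap.errors import AlignmentError, CalibrationError, CoverageError
from foodgap.gap import GapReport, gap_report
from foodgap.production import ProductionAccount

TERM_WINDOWS: dict[str, tuple[int, int]] = {
    "basic": (2011, 2030),
    "near": (2021, 2040),
    "mid": (2041, 2060),
}

SSP_IDS = ("SSP1-2.6", "SSP2-4.5", "SSP5-8.5")


@dataclass(frozen=True)
class ScenarioSpec:
    """One SSP scenario with its term windows and gap baseline year."""

    ssp_id: str
    windows: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(TERM_WINDOWS)
    )
    baseline_year: int = 2020

    def __post_init__(self) -> None:
        if self.ssp_id not in SSP_IDS:
            raise ValueError(f"unknown scenario {self.ssp_id!r}; expected one of {SSP_IDS}")
        for term, (lo, hi) in self.windows.items():
            if hi < lo:
                raise ValueError(f"window {term!r} is empty: {lo}-{hi}")


@dataclass
class ShareModel:
    """Constant per-cohort regional share of the provincial population.

    ``shares`` and ``correlations`` are indexed by cohort (the pyramid's
    (age_stage, sex, residence) MultiIndex). Correlation is NaN-flagged
    when only one overlapping year was available.
    """

    shares: pd.Series
    correlations: pd.Series
    n_years: int

    def __post_init__(self) -> None:
        if ((self.shares < 0) | (self.shares > 1)).any():
            raise ValueError("shares must lie in [0, 1]")


def _pyramids_to_frame(series: Mapping[int, PopulationPyramid]) -> pd.DataFrame:
    """Year × cohort matrix of counts."""
    return pd.DataFrame({y: p.counts for y, p in series.items()}).T.fillna(0.0)


def calibrate_share_model(
    regional: Mapping[int, PopulationPyramid],
    provincial: Mapping[int, PopulationPyramid],
) -> ShareModel:
    """Fit per-cohort shares on the overlapping years of two pyramid series.

    The share is the mean of regional/provincial per cohort and year;
    the fit quality is the Pearson correlation of the two annual series
    per cohort (undefined, NaN, with fewer than two overlapping years or
    a constant series).
    """
    years = sorted(set(regional) & set(provincial))
    if not years:
        raise CalibrationError("no overlapping years between regional and provincial series")
    reg = _pyramids_to_frame({y: regional[y] for y in years})
    prov = _pyramids_to_frame({y: provincial[y] for y in years})
    if list(reg.columns) != list(prov.columns):
        reg, prov = reg.align(prov, join="outer", fill_value=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = (reg / prov).replace([np.inf, -np.inf], np.nan)
    shares = ratios.mean(axis=0).fillna(0.0).clip(0.0, 1.0)
    if len(years) < 2:
        corr = pd.Series(np.nan, index=reg.columns)
    else:
        corr = pd.Series(
            {
                c: (
                    np.nan
                    if reg[c].std() == 0 or prov[c].std() == 0
                    else stats.pearsonr(reg[c], prov[c]).statistic
                )
                for c in reg.columns
            }
        )
    return ShareModel(shares=shares, correlations=corr, n_years=len(years))


def downscale_population(
    provincial: Mapping[int, PopulationPyramid],
    model: ShareModel,
) -> dict[int, PopulationPyramid]:
    """Regional cohort = provincial cohort × calibrated share, per year."""
    out = {}
    for year, pyr in provincial.items():
        missing = pyr.counts.index.difference(model.shares.index)
        if len(missing):
            raise AlignmentError(f"cohorts missing from share model: {list(missing)}")
        out[year] = PopulationPyramid(
            year, pyr.counts * model.shares.reindex(pyr.counts.index)
        )
    return out


def term_average(
    series: Mapping[int, PopulationPyramid],
    window: tuple[int, int],
) -> PopulationPyramid:
    """Arithmetic mean pyramid over an inclusive year window."""
    lo, hi = window
    wanted = list(range(lo, hi + 1))
    missing = [y for y in wanted if y not in series]
    if missing:
        raise CoverageError(f"series missing years {missing} for window {lo}-{hi}")
    frame = _pyramids_to_frame({y: series[y] for y in wanted})
    mean = frame.mean(axis=0)
    return PopulationPyramid(year=(lo + hi) // 2, counts=mean)


def project_demand(
    term_pyramid: PopulationPyramid,
    structure: DietaryStructure,
    factors: FactorTable,
    ecf: MacronutrientCoefficients | None = None,
    ssp_id: str | None = None,
    term: str | None = None,
) -> DemandAccount:
    """Demand account for one (scenario, term, structure) combination."""
    return build_demand_account(
        term_pyramid,
        structure,
        factors,
        ecf=ecf,
        tags={"ssp": ssp_id, "term": term, "structure": structure.id},
    )


def future_gap(
    projected: DemandAccount,
    baseline: ProductionAccount,
    floor: float = 0.0,
) -> GapReport:
    """Gap of projected demand against frozen baseline-year production."""
    return gap_report(projected, baseline, floor=floor)


def demand_growth_rates(accounts: Mapping[str, DemandAccount]) -> pd.Series:
    """Relative TCD growth of each term versus the basic term, in percent."""
    if "basic" not in accounts:
        raise KeyError("growth rates need a 'basic' term account")
    base = accounts["basic"].tcd
    if base <= 0:
        raise ValueError("basic-term demand must be positive")
    return pd.Series(
        {term: (acc.tcd - base) / base * 100.0 for term, acc in accounts.items()}
    )


def read_projection_csv(path) -> dict[str, dict[int, PopulationPyramid]]:
    """Read ``projection.csv`` (ssp, year, age_stage, sex, count).

    Projections carry no urban/rural split; residence is set to ``"all"``
    and dietary structures resolve it through their wildcard path.
    """
    df = pd.read_csv(path)
    needed = {"ssp", "year", "age_stage", "sex", "count"}
    if not needed <= set(df.columns):
        from foodgap.errors import SchemaError

        raise SchemaError(f"projection table needs columns {sorted(needed)}")
    out: dict[str, dict[int, PopulationPyramid]] = {}
    for (ssp, year), sub in df.groupby(["ssp", "year"]):
        counts = sub.assign(residence="all").set_index(
            ["age_stage", "sex", "residence"]
        )["count"]
        out.setdefault(str(ssp), {})[int(year)] = PopulationPyramid(int(year), counts)
    return out
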