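"""End-to-end report assembly and run manifests.

``run_assessment`` ties the pipeline together for observed years:
production accounting, demand accounting per requested dietary
structure, and gap reports at the three resolutions, all written as CSV
next to a JSON run manifest (command, config hash, input digests, seed,
package version) so a bundle is fully traceable and re-runnable.
``run_projection`` does the same for scenario demand against a frozen
baseline production account.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from foodgap.core_tables import FactorTable, MacronutrientCoefficients
from foodgap.demand import build_demand_account, read_intake_csv, read_pyramid_csv
from foodgap.gap import gap_report
from foodgap.production import (
    account_frame,
    build_production_account,
    read_production_csv,
)
from foodgap.projection import (
    ScenarioSpec,
    demand_growth_rates,
    future_gap,
    project_demand,
    read_projection_csv,
    term_average,
)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written once per output bundle."""

    command: str
    seed: int | None
    inputs: dict = field(default_factory=dict)
    config_hash: str = ""
    package_version: str = ""
    created: str = ""

    @classmethod
    def create(
        cls,
        command: str,
        input_paths: Sequence[Path],
        seed: int | None = None,
        config: Mapping | None = None,
    ) -> "RunManifest":
        from foodgap import __version__

        cfg = json.dumps(dict(config or {}), sort_keys=True, default=str)
        return cls(
            command=command,
            seed=seed,
            inputs={str(p): _digest(Path(p)) for p in input_paths},
            config_hash=hashlib.sha256(cfg.encode()).hexdigest()[:16],
            package_version=__version__,
            created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path


def run_assessment(
    production_csv: str | Path,
    pyramid_csv: str | Path,
    intake_csv: str | Path,
    factors: FactorTable,
    out_dir: str | Path,
    structures: Sequence[str] | None = None,
    ecf: MacronutrientCoefficients | None = None,
    floor: float = 0.0,
) -> Path:
    """Observed-year assessment: production, demand, and gap bundles."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ecf = ecf or MacronutrientCoefficients()

    production = read_production_csv(production_csv)
    pyramids = read_pyramid_csv(pyramid_csv)
    intake = read_intake_csv(intake_csv)
    wanted = list(structures) if structures else sorted(intake)

    accounts = {y: build_production_account(r, factors, ecf) for y, r in production.items()}
    account_frame(accounts.values()).to_csv(out_dir / "production_account.csv", index=False)

    demand_rows, gap_frames = [], []
    for sid in wanted:
        structure = intake[sid]
        for year, pyramid in pyramids.items():
            dem = build_demand_account(pyramid, structure, factors, ecf=ecf)
            demand_rows.append(
                {
                    "structure": sid,
                    "year": year,
                    "total_bkcal": dem.tcd / 1e9,
                    "carbohydrate_kt": dem.mnd_q["carbohydrate"] / 1e9,
                    "protein_kt": dem.mnd_q["protein"] / 1e9,
                    "fat_kt": dem.mnd_q["fat"] / 1e9,
                }
            )
            if year in accounts:
                rep = gap_report(dem, accounts[year], floor=floor)
                t = rep.table.copy()
                t.insert(0, "structure", sid)
                t.insert(1, "year", year)
                t["convention"] = rep.convention
                gap_frames.append(t)
    pd.DataFrame(demand_rows).to_csv(out_dir / "demand_account.csv", index=False)
    if gap_frames:
        pd.concat(gap_frames, ignore_index=True).to_csv(
            out_dir / "gap_report.csv", index=False
        )

    manifest = RunManifest.create(
        "assessment",
        [Path(production_csv), Path(pyramid_csv), Path(intake_csv)],
        config={"structures": wanted, "floor": floor, "factors": factors.provenance},
    )
    return manifest.write(out_dir)


def run_projection(
    scenario: ScenarioSpec,
    projection_csv: str | Path,
    intake_csv: str | Path,
    baseline_production_csv: str | Path,
    factors: FactorTable,
    out_dir: str | Path,
    structures: Sequence[str] | None = None,
    ecf: MacronutrientCoefficients | None = None,
) -> Path:
    """Scenario projection: per-(term, structure) demand and future gaps."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ecf = ecf or MacronutrientCoefficients()

    projections = read_projection_csv(projection_csv)
    if scenario.ssp_id not in projections:
        raise KeyError(f"scenario {scenario.ssp_id!r} absent from projection file")
    series = projections[scenario.ssp_id]
    intake = read_intake_csv(intake_csv)
    wanted = list(structures) if structures else sorted(intake)

    baseline_records = read_production_csv(baseline_production_csv)
    if scenario.baseline_year not in baseline_records:
        raise KeyError(f"baseline year {scenario.baseline_year} absent from production file")
    baseline = build_production_account(
        baseline_records[scenario.baseline_year], factors, ecf
    )

    demand_rows, gap_frames, growth_rows = [], [], []
    for sid in wanted:
        structure = intake[sid]
        per_term = {}
        for term, window in scenario.windows.items():
            pyr = term_average(series, window)
            dem = project_demand(
                pyr, structure, factors, ecf=ecf, ssp_id=scenario.ssp_id, term=term
            )
            per_term[term] = dem
            demand_rows.append(
                {
                    "ssp": scenario.ssp_id,
                    "term": term,
                    "structure": sid,
                    "total_bkcal": dem.tcd / 1e9,
                    "carbohydrate_kt": dem.mnd_q["carbohydrate"] / 1e9,
                    "protein_kt": dem.mnd_q["protein"] / 1e9,
                    "fat_kt": dem.mnd_q["fat"] / 1e9,
                }
            )
            rep = future_gap(dem, baseline)
            t = rep.table.copy()
            t.insert(0, "ssp", scenario.ssp_id)
            t.insert(1, "term", term)
            t.insert(2, "structure", sid)
            gap_frames.append(t)
        for term, rate in demand_growth_rates(per_term).items():
            growth_rows.append(
                {
                    "ssp": scenario.ssp_id,
                    "structure": sid,
                    "term": term,
                    "tcd_growth_pct_vs_basic": rate,
                }
            )
    pd.DataFrame(demand_rows).to_csv(out_dir / "future_demand.csv", index=False)
    pd.concat(gap_frames, ignore_index=True).to_csv(out_dir / "future_gap.csv", index=False)
    pd.DataFrame(growth_rows).to_csv(out_dir / "growth_rates.csv", index=False)

    manifest = RunManifest.create(
        "projection",
        [Path(projection_csv), Path(intake_csv), Path(baseline_production_csv)],
        config={
            "ssp": scenario.ssp_id,
            "windows": {k: list(v) for k, v in scenario.windows.items()},
            "baseline_year": scenario.baseline_year,
            "structures": wanted,
        },
    )
    return manifest.write(out_dir)
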