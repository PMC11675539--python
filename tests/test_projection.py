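"""Downscaling, term averaging, scenario demand, and future gaps."""

import numpy as np
import pandas as pd
import pytest

from foodgap.core_tables import FOOD_NAMES
from foodgap.demand import PopulationPyramid
from foodgap.errors import CalibrationError, CoverageError
from foodgap.production import ProductionRecord, build_production_account
from foodgap.projection import (
    ScenarioSpec,
    calibrate_share_model,
    demand_growth_rates,
    downscale_population,
    future_gap,
    project_demand,
    term_average,
)
from foodgap.synthetic import GeneratorConfig, gen_population_pyramid

from conftest import make_pyramid, make_uniform_structure


class TestScenarioSpec:
    def test_default_term_windows(self):
        spec = ScenarioSpec("SSP2-4.5")
        assert spec.windows == {
            "basic": (2011, 2030),
            "near": (2021, 2040),
            "mid": (2041, 2060),
        }
        assert spec.baseline_year == 2020

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("SSP3-7.0")


class TestCalibration:
    def test_exact_proportionality_recovers_share_and_unit_correlation(self):
        cfg = GeneratorConfig(seed=3, noise_cv=0.0, regional_share=0.4, n_years=5)
        regional, provincial = gen_population_pyramid(cfg)
        model = calibrate_share_model(regional, provincial)
        np.testing.assert_allclose(model.shares, 0.4, rtol=1e-12)
        np.testing.assert_allclose(model.correlations.dropna(), 1.0, rtol=1e-9)

    def test_single_year_share_defined_correlation_flagged(self):
        cfg = GeneratorConfig(seed=3, noise_cv=0.0, regional_share=0.4, n_years=1)
        regional, provincial = gen_population_pyramid(cfg)
        model = calibrate_share_model(regional, provincial)
        np.testing.assert_allclose(model.shares, 0.4, rtol=1e-12)
        assert model.correlations.isna().all()
        assert model.n_years == 1

    def test_no_overlap_is_a_calibration_error(self):
        cfg = GeneratorConfig(seed=3, n_years=2)
        regional, provincial = gen_population_pyramid(cfg)
        shifted = {y + 100: p for y, p in provincial.items()}
        with pytest.raises(CalibrationError):
            calibrate_share_model(regional, shifted)

    def test_noisy_share_recovery_within_two_noise_standard_errors(self):
        # Mean-of-ratios carries a Jensen bias ~ share x cv^2 under
        # log-normal noise; the single-recovery spread dominates it.
        estimates = []
        for seed in range(30):
            cfg = GeneratorConfig(seed=seed, noise_cv=0.02, regional_share=0.35)
            regional, provincial = gen_population_pyramid(cfg)
            model = calibrate_share_model(regional, provincial)
            estimates.append(model.shares.mean())
        spread = np.std(estimates, ddof=1)
        assert abs(np.mean(estimates) - 0.35) < 2 * max(spread, 1e-4)


class TestDownscaling:
    def test_share_one_is_identity(self):
        cfg = GeneratorConfig(seed=5, noise_cv=0.0, regional_share=1.0, n_years=3)
        _, provincial = gen_population_pyramid(cfg)
        model = calibrate_share_model(provincial, provincial)
        region = downscale_population(provincial, model)
        for y in provincial:
            pd.testing.assert_series_equal(region[y].counts, provincial[y].counts)

    def test_share_zero_empties_the_region(self):
        cfg = GeneratorConfig(seed=5, noise_cv=0.0, regional_share=0.0, n_years=3)
        regional, provincial = gen_population_pyramid(cfg)
        model = calibrate_share_model(regional, provincial)
        region = downscale_population(provincial, model)
        assert all(r.total == 0 for r in region.values())

    def test_matches_per_cell_multiplication_oracle(self, rng):
        cfg = GeneratorConfig(seed=6, noise_cv=0.05, regional_share=0.3, n_years=4)
        regional, provincial = gen_population_pyramid(cfg)
        model = calibrate_share_model(regional, provincial)
        region = downscale_population(provincial, model)
        for y, pyr in provincial.items():
            for cohort, count in pyr.counts.items():
                assert region[y].counts[cohort] == pytest.approx(
                    count * model.shares[cohort], rel=1e-12
                )

    def test_downscale_then_sum_equals_sum_then_downscale_for_common_share(self):
        cfg = GeneratorConfig(seed=7, noise_cv=0.0, regional_share=0.25, n_years=3)
        regional, provincial = gen_population_pyramid(cfg)
        model = calibrate_share_model(regional, provincial)
        region = downscale_population(provincial, model)
        for y in provincial:
            assert region[y].total == pytest.approx(0.25 * provincial[y].total, rel=1e-9)


class TestTermAverage:
    def _series(self, values_by_year):
        idx = pd.MultiIndex.from_tuples([("18-49", "female", "urban")])
        return {
            y: PopulationPyramid(y, pd.Series([v], index=idx, dtype=float))
            for y, v in values_by_year.items()
        }

    def test_constant_series(self):
        series = self._series({y: 100.0 for y in range(2011, 2031)})
        avg = term_average(series, (2011, 2030))
        assert avg.counts.iloc[0] == pytest.approx(100.0)

    def test_linear_series_gives_midpoint(self):
        series = self._series({y: float(y) for y in range(2011, 2031)})
        avg = term_average(series, (2011, 2030))
        assert avg.counts.iloc[0] == pytest.approx((2011 + 2030) / 2)

    def test_missing_years_listed(self):
        series = self._series({y: 1.0 for y in range(2011, 2029)})
        with pytest.raises(CoverageError, match="2030"):
            term_average(series, (2011, 2030))

    def test_random_series_matches_loop_mean_oracle(self, rng):
        vals = {y: rng.uniform(0, 1e6) for y in range(2021, 2041)}
        series = self._series(vals)
        avg = term_average(series, (2021, 2040))
        assert avg.counts.iloc[0] == pytest.approx(
            sum(vals.values()) / len(vals), rel=1e-12
        )


class TestProjectedDemandAndFutureGap:
    def test_zero_pyramid_gives_zero_demand(self, rng, factors):
        pyr = PopulationPyramid.uniform(2030, 0.0)
        acc = project_demand(pyr, make_uniform_structure(rng), factors)
        assert acc.tcd == 0.0

    def test_structure_dominance_carries_to_projection(self, rng, factors):
        from foodgap.synthetic import gen_intake_tables

        _, s1, s2 = gen_intake_tables(GeneratorConfig(seed=9))
        pyr = make_pyramid(rng)
        assert project_demand(pyr, s1, factors).tcd >= project_demand(pyr, s2, factors).tcd

    def test_demand_equal_to_baseline_production_gaps_zero(self, rng, factors, ecf):
        rec = ProductionRecord(
            2020, pd.Series(rng.uniform(1e10, 1e12, 9), index=list(FOOD_NAMES))
        )
        baseline = build_production_account(rec, factors, ecf)
        from foodgap.demand import DemandAccount

        dem = DemandAccount(
            year=2030,
            structure_id="S1",
            tcd_j=baseline.tcp_j.copy(),
            tcd=baseline.tcp,
            mnd=baseline.mnp.copy(),
            mnd_q=baseline.mnp_q.copy(),
        )
        rep = future_gap(dem, baseline)
        assert (rep.table["gap_pct"].abs() < 1e-9).all()
        assert (rep.table["flag"] == "met").all()

    def test_doubled_demand_gaps_one_hundred_percent(self, rng, factors, ecf):
        rec = ProductionRecord(
            2020, pd.Series(rng.uniform(1e10, 1e12, 9), index=list(FOOD_NAMES))
        )
        baseline = build_production_account(rec, factors, ecf)
        from foodgap.demand import DemandAccount

        dem = DemandAccount(
            year=2030,
            structure_id="S1",
            tcd_j=baseline.tcp_j * 2,
            tcd=baseline.tcp * 2,
            mnd=baseline.mnp * 2,
            mnd_q=baseline.mnp_q * 2,
        )
        rep = future_gap(dem, baseline)
        np.testing.assert_allclose(rep.table["gap_pct"], 100.0, rtol=1e-9)

    def test_growth_rates_invariant_across_age_invariant_structures(self, factors):
        # For uniform structures, TCD ∝ total population × Σ_j FI_j CalF_j,
        # so relative growth between terms is structure-free.
        terms = {
            "basic": PopulationPyramid.uniform(2020, 100.0),
            "near": PopulationPyramid.uniform(2030, 121.0),
            "mid": PopulationPyramid.uniform(2050, 155.0),
        }
        rng = np.random.default_rng(11)
        rates = []
        for sid in ("A", "B"):
            structure = make_uniform_structure(rng, sid)
            accounts = {
                t: project_demand(p, structure, factors) for t, p in terms.items()
            }
            rates.append(demand_growth_rates(accounts))
        pd.testing.assert_series_equal(rates[0], rates[1])
        assert rates[0]["near"] == pytest.approx(21.0)
        assert rates[0]["mid"] == pytest.approx(55.0)
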