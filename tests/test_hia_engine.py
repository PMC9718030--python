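"""Attributable deaths, YLL, LLE, rates and aggregation."""

import numpy as np
import pandas as pd
import pytest

from microsim_oracle import cohort_life_expectancies
from pmhia import (
    LogLinearRisk,
    MortalitySchedule,
    Scenario,
    attributable_deaths,
    build_life_table,
    exposure_summary,
    loss_of_life_expectancy,
    perturb_schedule,
    rate_per_100k,
    run_comparison,
    run_hia,
    years_of_life_lost,
)
from pmhia.hia_engine import age_group_attributable_fractions, aggregate, unit_summary
from pmhia.risk_models import GEMMParameterSet, GEMMParams

from conftest import make_schedule


def _interval_ordered(df, base):
    return (
        (df[f"{base}_low"] <= df[base] + 1e-12)
        & (df[base] <= df[f"{base}_high"] + 1e-12)
    ).all()


class TestAttributableDeaths:
    def test_exposure_at_counterfactual_gives_zero(self, simple_schedule, gemm):
        imp = attributable_deaths(simple_schedule, 5.0, Scenario("AQG", 5.0), gemm=gemm)
        assert (imp[["ad_low", "ad", "ad_high"]] == 0).all().all()

    def test_forced_fraction_arithmetic(self):
        """One open band, 10,000 people at rate 0.01, AF pinned to 0.2 by a
        degenerate log-linear risk (RR=1.25 over a 10-unit excess) -> 20 deaths."""
        schedule = MortalitySchedule(
            ("85+",), np.array([10_000.0]), np.array([100.0]), unit_id="one-band"
        )
        risk = LogLinearRisk(1.25, 1.25, 1.25)
        scenario = Scenario("stub", 5.0, risk_model="log-linear")
        imp = attributable_deaths(schedule, 15.0, scenario, loglinear=risk)
        assert imp["ad"].sum() == pytest.approx(20.0)

    def test_aqg_burden_exceeds_qcvn_burden(self, simple_schedule, gemm):
        """Ha-Noi-like exposure: the stricter counterfactual attributes more."""
        aqg = attributable_deaths(simple_schedule, 40.8, Scenario("AQG", 5.0), gemm=gemm)
        qcvn = attributable_deaths(
            simple_schedule, 40.8, Scenario("QCVN", 15.0), gemm=gemm
        )
        assert aqg["ad"].sum() > qcvn["ad"].sum() > 0
        assert _interval_ordered(aqg, "ad") and _interval_ordered(qcvn, "ad")

    def test_ad_bounded_by_observed_deaths(self, simple_schedule, gemm):
        imp = attributable_deaths(simple_schedule, 150.0, Scenario("AQG", 5.0), gemm=gemm)
        adult = simple_schedule.restrict(25)
        deaths = pd.Series(adult.deaths, index=list(adult.age_groups))
        assert (imp["ad_high"].to_numpy() <= deaths.loc[imp["age_group"]].to_numpy()).all()

    def test_montecarlo_interval_close_to_delta(self, simple_schedule, gemm):
        delta = attributable_deaths(simple_schedule, 30.0, Scenario("AQG", 5.0), gemm=gemm)
        mc = attributable_deaths(
            simple_schedule, 30.0, Scenario("AQG", 5.0), gemm=gemm,
            ci_method="montecarlo", n_draws=4000, seed=11,
        )
        assert mc["ad"].sum() == pytest.approx(delta["ad"].sum())
        assert mc["ad_low"].sum() == pytest.approx(delta["ad_low"].sum(), rel=0.05)
        assert mc["ad_high"].sum() == pytest.approx(delta["ad_high"].sum(), rel=0.05)


class TestYearsOfLifeLost:
    def test_zero_deaths_zero_yll(self, simple_schedule, gemm):
        imp = attributable_deaths(simple_schedule, 5.0, Scenario("AQG", 5.0), gemm=gemm)
        out = years_of_life_lost(imp, build_life_table(simple_schedule))
        assert (out[["yll_low", "yll", "yll_high"]] == 0).all().all()

    def test_single_band_arithmetic(self, simple_schedule):
        table = build_life_table(simple_schedule)
        imp = pd.DataFrame(
            {
                "unit_id": ["u"], "age_group": ["60-64"],
                "af_low": [0.1], "af": [0.1], "af_high": [0.1],
                "ad_low": [10.0], "ad": [10.0], "ad_high": [10.0],
            }
        )
        out = years_of_life_lost(imp, table)
        assert out["yll"].iloc[0] == pytest.approx(10.0 * table.ex("60-64"))

    def test_total_matches_sum_product_oracle(self, simple_schedule, gemm):
        table = build_life_table(simple_schedule)
        imp = attributable_deaths(simple_schedule, 35.0, Scenario("AQG", 5.0), gemm=gemm)
        out = years_of_life_lost(imp, table)
        oracle = sum(
            ad * table.ex(g) for ad, g in zip(imp["ad"], imp["age_group"])
        )
        assert out["yll"].sum() == pytest.approx(oracle, rel=1e-12)

    def test_band_mismatch_rejected(self, simple_schedule):
        table = build_life_table(simple_schedule.restrict(40))
        imp = pd.DataFrame(
            {"age_group": ["25-29"], "ad_low": [1.0], "ad": [1.0], "ad_high": [1.0]}
        )
        with pytest.raises(KeyError, match="25-29"):
            years_of_life_lost(imp, table)


class TestLossOfLifeExpectancy:
    def test_no_fraction_no_loss(self, simple_schedule):
        assert loss_of_life_expectancy(simple_schedule, {}) == 0.0

    def test_any_fraction_positive_loss(self, simple_schedule):
        assert loss_of_life_expectancy(simple_schedule, {"45-49": 0.3}) > 0.0

    def test_adult_only_schedule_rejected(self, simple_schedule):
        with pytest.raises(ValueError, match="birth"):
            loss_of_life_expectancy(simple_schedule.restrict(25), {"45-49": 0.1})

    def test_cross_checked_against_microsimulation(self, simple_schedule, gemm):
        """e0 under both the observed and counterfactual rate sets agrees with
        the cohort simulation, and the implied LLE difference matches."""
        afs = age_group_attributable_fractions(
            40.8, Scenario("AQG", 5.0), simple_schedule.restrict(25).age_groups,
            gemm=gemm,
        )
        af_map = dict(zip(afs["age_group"], afs["af"]))
        perturbed = perturb_schedule(simple_schedule, af_map)
        e0_obs = build_life_table(simple_schedule).e0
        e0_cf = build_life_table(perturbed).e0
        sim_obs = cohort_life_expectancies(
            simple_schedule.starts, simple_schedule.rates, n=1_000_000, seed=1
        )[0]
        sim_cf = cohort_life_expectancies(
            perturbed.starts, perturbed.rates, n=1_000_000, seed=2
        )[0]
        assert e0_obs == pytest.approx(sim_obs, rel=5e-3)
        assert e0_cf == pytest.approx(sim_cf, rel=5e-3)
        lle = loss_of_life_expectancy(simple_schedule, af_map)
        assert lle == pytest.approx(e0_cf - e0_obs, rel=1e-12)
        assert lle == pytest.approx(sim_cf - sim_obs, abs=0.15)


class TestRates:
    def test_rate_arithmetic(self):
        assert rate_per_100k(0.0, 123.0) == 0.0
        assert rate_per_100k(50.0, 100_000.0) == 50.0
        assert rate_per_100k(5090, 8_050_000) == pytest.approx(5090 / 8_050_000 * 1e5)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            rate_per_100k(10.0, 0.0)


class TestAggregation:
    def _impacts(self, schedule, exposure, gemm):
        imp = attributable_deaths(schedule, exposure, Scenario("AQG", 5.0), gemm=gemm)
        return years_of_life_lost(imp, build_life_table(schedule))

    def test_single_district_province_is_identity(self, simple_schedule, gemm):
        scenario = Scenario("AQG", 5.0)
        imp = self._impacts(simple_schedule, 30.0, gemm)
        prov, region = aggregate(
            {"simple": imp}, {"simple": simple_schedule}, {"simple": "P"},
            scenario, {"simple": 30.0},
        )
        district_row = unit_summary(simple_schedule, imp, scenario, 30.0)
        for col in ("ad", "yll", "ad_rate", "lle_years"):
            assert prov[col].iloc[0] == pytest.approx(district_row[col])
            assert region[col].iloc[0] == pytest.approx(district_row[col])

    def test_counts_sum_over_districts(self, gemm):
        rng = np.random.default_rng(0)
        mids = np.array([s + 2.5 for s in range(0, 85, 5)] + [90.0])
        scheds = {
            u: make_schedule(
                4e-5 * np.exp(0.09 * mids) + 5e-4,
                population=rng.uniform(5_000, 20_000, 18),
                unit_id=u,
            )
            for u in ("d1", "d2")
        }
        exposures = {"d1": 25.0, "d2": 35.0}
        scenario = Scenario("AQG", 5.0)
        impacts = {u: self._impacts(scheds[u], exposures[u], gemm) for u in scheds}
        prov, region = aggregate(
            impacts, scheds, {"d1": "P", "d2": "P"}, scenario, exposures
        )
        expected_ad = sum(impacts[u]["ad"].sum() for u in scheds)
        assert prov["ad"].iloc[0] == pytest.approx(expected_ad)
        assert region["ad"].iloc[0] == pytest.approx(expected_ad)
        # rates recomputed from pooled counts and denominators, not averaged
        denom = sum(s.total_population for s in scheds.values())
        assert prov["ad_rate"].iloc[0] == pytest.approx(expected_ad / denom * 1e5)

    def test_orphan_district_rejected(self, simple_schedule, gemm):
        imp = self._impacts(simple_schedule, 30.0, gemm)
        with pytest.raises(ValueError, match="without a province"):
            aggregate({"simple": imp}, {"simple": simple_schedule}, {},
                      Scenario("AQG", 5.0), {"simple": 30.0})


class TestRunHIA:
    def test_null_exposure_surface_all_zero(self, simple_schedule, gemm):
        """Every unit at the counterfactual: impacts and LLE exactly zero."""
        result = run_hia(
            {"simple": simple_schedule}, {"simple": 5.0}, Scenario("AQG", 5.0),
            gemm=gemm,
        )
        row = result.district.iloc[0]
        assert row["ad"] == 0 and row["yll"] == 0 and row["lle_years"] == 0
        assert bool(row["below_counterfactual"])
        assert result.region["lle_years"].iloc[0] == 0

    def test_scale_invariance(self, simple_schedule, gemm):
        """Doubling population and deaths doubles AD/YLL but not rates or LLE."""
        doubled = MortalitySchedule(
            simple_schedule.age_groups,
            simple_schedule.population * 2,
            simple_schedule.deaths * 2,
            unit_id="doubled",
        )
        r1 = run_hia({"u": simple_schedule}, {"u": 30.0}, Scenario("AQG", 5.0), gemm=gemm)
        r2 = run_hia({"u": doubled}, {"u": 30.0}, Scenario("AQG", 5.0), gemm=gemm)
        a, b = r1.district.iloc[0], r2.district.iloc[0]
        assert b["ad"] == pytest.approx(2 * a["ad"])
        assert b["yll"] == pytest.approx(2 * a["yll"])
        assert b["ad_rate"] == pytest.approx(a["ad_rate"])
        assert b["lle_years"] == pytest.approx(a["lle_years"])

    def test_interval_ordering_all_levels(self, calibrated_run, gemm):
        schedules, mapping, exposures = calibrated_run
        result = run_hia(
            schedules, exposures, Scenario("AQG", 5.0), gemm=gemm,
            unit_to_province=mapping,
        )
        for frame in (result.district, result.province, result.region):
            for base in ("ad", "ad_rate", "yll", "yll_rate", "lle_years"):
                assert _interval_ordered(frame, base)

    def test_adults_only_denominator_raises_rates(self, simple_schedule, gemm):
        total = run_hia({"u": simple_schedule}, {"u": 30.0}, Scenario("AQG", 5.0), gemm=gemm)
        adults = run_hia(
            {"u": simple_schedule}, {"u": 30.0},
            Scenario("AQG", 5.0, rate_denominator="adults-only"), gemm=gemm,
        )
        assert adults.district["ad_rate"].iloc[0] > total.district["ad_rate"].iloc[0]
        assert adults.district["ad"].iloc[0] == pytest.approx(
            total.district["ad"].iloc[0]
        )


class TestComparison:
    def test_exposure_at_counterfactual_zeroes_both_columns(self, simple_schedule, gemm):
        out = run_comparison({"u": simple_schedule}, {"u": 5.0}, gemm=gemm)
        assert out["ad_rate_loglinear"].iloc[0] == 0.0
        assert out["ad_rate_gemm"].iloc[0] == 0.0

    def test_doubled_theta_raises_gemm_column(self, simple_schedule, gemm):
        doubled = GEMMParameterSet(
            {
                g: GEMMParams(g, gemm[g].theta * 2, gemm[g].theta_se,
                              gemm[g].alpha, gemm[g].mu, gemm[g].nu)
                for g in gemm
            }
        )
        base = run_comparison({"u": simple_schedule}, {"u": 30.0}, gemm=gemm)
        boosted = run_comparison({"u": simple_schedule}, {"u": 30.0}, gemm=doubled)
        assert boosted["ad_rate_gemm"].iloc[0] > base["ad_rate_gemm"].iloc[0]
        assert boosted["ad_rate_loglinear"].iloc[0] == pytest.approx(
            base["ad_rate_loglinear"].iloc[0]
        )

    def test_loglinear_column_uses_30plus_population(self, simple_schedule, gemm):
        out = run_comparison({"u": simple_schedule}, {"u": 30.0}, gemm=gemm)
        assert out["pop_loglinear"].iloc[0] == pytest.approx(
            simple_schedule.restrict(30).total_population
        )
        assert out["pop_gemm"].iloc[0] == pytest.approx(
            simple_schedule.total_population
        )


class TestExposureSummary:
    def test_hanoi_exceedance_ratio(self, province_table):
        exposures = dict(
            zip(province_table["province"], province_table["pm25_annual_mean"])
        )
        out = exposure_summary(exposures, {"QCVN": 15.0})
        assert out["ratios"].loc["Ha Noi", "ratio_QCVN"] == 2.72

    def test_unit_equal_to_threshold(self):
        out = exposure_summary({"u": 15.0}, {"QCVN": 15.0})
        assert out["ratios"].loc["u", "ratio_QCVN"] == 1.00

    def test_min_max_and_validation(self, province_table):
        exposures = dict(
            zip(province_table["province"], province_table["pm25_annual_mean"])
        )
        out = exposure_summary(exposures)
        assert (out["min"], out["max"]) == (15.8, 40.8)
        with pytest.raises(ValueError, match="threshold"):
            exposure_summary(exposures, {"bad": 0.0})
        with pytest.raises(ValueError, match="empty"):
            exposure_summary({})
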