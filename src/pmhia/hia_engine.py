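"""Attributable-mortality pipeline for counterfactual PM2.5 scenarios.

For each administrative unit the engine takes an annual-mean PM2.5 exposure
and an all-age mortality schedule and computes, per 5-year adult age group:

* the attributable fraction AF = 1 - HR(c_cf)/HR(c_obs) under the scenario's
  risk model (GEMM NCD+LRI or the AirQ+-style log-linear model),
* attributable deaths AD = deaths * AF,
* years of life lost YLL = AD * ex, with ex the remaining life expectancy of
  the band from the unit's baseline abridged life table,

and, per unit, the loss of life expectancy at birth (LLE): the gain in
life-table e0 when the attributable deaths are removed from the schedule.
Units whose exposure does not exceed the scenario counterfactual are kept in
every output with zero impact and a ``below_counterfactual`` flag.

Uncertainty is propagated by evaluating the whole pipeline at theta and
theta +/- 1.96*SE(theta) per age group (treated as perfectly correlated
across ages), or optionally by seeded Monte-Carlo draws of theta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .life_table import (
    LifeTable,
    MortalitySchedule,
    build_life_table,
    perturb_schedule,
    pool_schedules,
)
from .risk_models import (
    GEMMParameterSet,
    LogLinearRisk,
    attributable_fraction,
    gemm_hazard_ratio,
    loglinear_rr,
)

__all__ = [
    "Scenario",
    "HIAResult",
    "age_group_attributable_fractions",
    "attributable_deaths",
    "years_of_life_lost",
    "loss_of_life_expectancy",
    "rate_per_100k",
    "unit_summary",
    "aggregate",
    "run_hia",
    "run_comparison",
    "exposure_summary",
]

DAYS_PER_YEAR = 365.25

GEMM_MIN_AGE = 25          # GEMM NCD+LRI applies to adults 25+
LOGLINEAR_MIN_AGE = 30     # the log-linear meta-analytic RR applies to 30+


@dataclass(frozen=True)
class Scenario:
    """A named counterfactual concentration plus risk-model choice."""

    name: str
    counterfactual: float  # ug/m3 (e.g. AQG 5, proposed QCVN 15)
    risk_model: str = "gemm"  # "gemm" | "log-linear"
    rate_denominator: str = "total-population"  # or "adults-only"

    def __post_init__(self) -> None:
        if self.counterfactual < 0:
            raise ValueError(
                f"counterfactual must be >= 0 ug/m3, got {self.counterfactual}"
            )
        if self.risk_model not in ("gemm", "log-linear"):
            raise ValueError(f"unknown risk model {self.risk_model!r}")
        if self.rate_denominator not in ("total-population", "adults-only"):
            raise ValueError(
                f"unknown rate denominator {self.rate_denominator!r}"
            )

    @property
    def min_age(self) -> int:
        return GEMM_MIN_AGE if self.risk_model == "gemm" else LOGLINEAR_MIN_AGE


def age_group_attributable_fractions(
    exposure: float,
    scenario: Scenario,
    age_groups: Sequence[str],
    gemm: GEMMParameterSet | None = None,
    loglinear: LogLinearRisk | None = None,
    ci_method: str = "delta",
    n_draws: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """AF (low, point, high) per adult age group for one exposure value.

    ``ci_method="delta"`` evaluates the closed form at theta +/- 1.96*SE;
    ``"montecarlo"`` draws a standard-normal deviate per replicate, shared
    across age groups (perfectly correlated), and reports 2.5/97.5
    percentiles.
    """
    if exposure < 0:
        raise ValueError(f"exposure must be >= 0 ug/m3, got {exposure}")
    cf = scenario.counterfactual
    rows = []
    if exposure <= cf:
        for g in age_groups:
            rows.append((g, 0.0, 0.0, 0.0))
        return pd.DataFrame(rows, columns=["age_group", "af_low", "af", "af_high"])

    if scenario.risk_model == "gemm":
        if gemm is None:
            gemm = GEMMParameterSet.default()
        if ci_method == "montecarlo":
            rng = np.random.default_rng(seed)
            zdraws = rng.standard_normal(n_draws)
        for g in age_groups:
            p = gemm[g]

            def _af(theta: float) -> float:
                return attributable_fraction(
                    gemm_hazard_ratio(exposure, p, theta_override=theta),
                    gemm_hazard_ratio(cf, p, theta_override=theta),
                )

            point = _af(p.theta)
            if ci_method == "delta":
                lo = _af(p.theta - 1.96 * p.theta_se)
                hi = _af(p.theta + 1.96 * p.theta_se)
            elif ci_method == "montecarlo":
                sims = np.array([_af(p.theta + z * p.theta_se) for z in zdraws])
                lo, hi = np.percentile(sims, [2.5, 97.5])
            else:
                raise ValueError(f"unknown ci_method {ci_method!r}")
            lo, hi = min(lo, point), max(hi, point)
            rows.append((g, lo, point, hi))
    else:
        if loglinear is None:
            loglinear = LogLinearRisk()
        af_point = attributable_fraction(
            loglinear_rr(exposure, cf, loglinear), 1.0
        )
        af_lo = attributable_fraction(
            loglinear_rr(exposure, cf, loglinear, rr_per_10=loglinear.ci_low_per_10),
            1.0,
        )
        af_hi = attributable_fraction(
            loglinear_rr(exposure, cf, loglinear, rr_per_10=loglinear.ci_high_per_10),
            1.0,
        )
        for g in age_groups:
            rows.append((g, af_lo, af_point, af_hi))
    return pd.DataFrame(rows, columns=["age_group", "af_low", "af", "af_high"])


def attributable_deaths(
    schedule: MortalitySchedule,
    exposure: float,
    scenario: Scenario,
    gemm: GEMMParameterSet | None = None,
    loglinear: LogLinearRisk | None = None,
    **ci_kwargs,
) -> pd.DataFrame:
    """Per-age-group attributable deaths for one unit.

    ``ad_a = population_a * rate_a * AF_a`` (equivalently ``deaths_a * AF_a``),
    on the adult bands the scenario's risk model covers.  Returns a frame
    with unit_id, age_group, the AF triplet and the AD triplet.
    """
    adult = schedule.restrict(scenario.min_age)
    afs = age_group_attributable_fractions(
        exposure, scenario, adult.age_groups, gemm=gemm, loglinear=loglinear,
        **ci_kwargs,
    )
    deaths = pd.Series(adult.deaths, index=list(adult.age_groups))
    out = afs.copy()
    out.insert(0, "unit_id", schedule.unit_id)
    for col, afcol in (("ad_low", "af_low"), ("ad", "af"), ("ad_high", "af_high")):
        out[col] = deaths.loc[out["age_group"]].to_numpy() * out[afcol].to_numpy()
    return out


def years_of_life_lost(
    impacts: pd.DataFrame, baseline_table: LifeTable
) -> pd.DataFrame:
    """Fill YLL columns: ``yll_a = ad_a * ex_a`` with bounds from the AD bounds."""
    ex = {
        g: baseline_table.ex(g) for g in impacts["age_group"].unique()
    }  # raises on band mismatch
    out = impacts.copy()
    exv = out["age_group"].map(ex).to_numpy()
    for col, adcol in (("yll_low", "ad_low"), ("yll", "ad"), ("yll_high", "ad_high")):
        out[col] = out[adcol].to_numpy() * exv
    return out


def loss_of_life_expectancy(
    schedule: MortalitySchedule,
    af_by_band: Mapping[str, float],
    nax_closed: float = 2.5,
    a0: float | None = None,
) -> float:
    """Loss of life expectancy at birth (years) due to the attributable deaths.

    Subtracts baseline e0 from the e0 of the counterfactual schedule with the
    attributable fraction of deaths removed.  The difference is computed in
    days and converted back to years (/365.25).  Requires an all-age
    schedule: e0 is defined at birth.
    """
    if schedule.starts[0] != 0:
        raise ValueError(
            "LLE is the loss of life expectancy at birth and needs a schedule "
            f"starting at age 0; got first band {schedule.age_groups[0]!r}"
        )
    e0_obs = build_life_table(schedule, nax_closed=nax_closed, a0=a0).e0
    e0_cf = build_life_table(
        perturb_schedule(schedule, af_by_band), nax_closed=nax_closed, a0=a0
    ).e0
    lle_days = (e0_cf - e0_obs) * DAYS_PER_YEAR
    return lle_days / DAYS_PER_YEAR


def rate_per_100k(count: float, denominator: float) -> float:
    """Events per year per 100,000 persons."""
    if denominator <= 0:
        raise ValueError(f"denominator population must be > 0, got {denominator}")
    return count / denominator * 100_000.0


def _af_maps(impacts: pd.DataFrame, deaths: pd.Series) -> dict[str, dict[str, float]]:
    """Per-band AF maps (low/point/high) implied by AD and baseline deaths."""
    maps: dict[str, dict[str, float]] = {"low": {}, "point": {}, "high": {}}
    for _, row in impacts.iterrows():
        d = deaths.get(row["age_group"], 0.0)
        if d <= 0:
            continue
        for key, col in (("low", "ad_low"), ("point", "ad"), ("high", "ad_high")):
            maps[key][row["age_group"]] = min(row[col] / d, 1.0 - 1e-12)
    return maps


def unit_summary(
    schedule: MortalitySchedule,
    impacts: pd.DataFrame,
    scenario: Scenario,
    exposure: float,
    level: str = "district",
    nax_closed: float = 2.5,
    a0: float | None = None,
) -> dict:
    """One summary row: AD, YLL (counts and rates per 100,000) and LLE."""
    if scenario.rate_denominator == "total-population":
        denom = schedule.total_population
    else:
        denom = schedule.restrict(GEMM_MIN_AGE).total_population
    deaths = pd.Series(schedule.deaths, index=list(schedule.age_groups))
    afm = _af_maps(impacts, deaths)
    row: dict = {
        "unit_id": schedule.unit_id,
        "level": level,
        "scenario": scenario.name,
        "exposure": exposure,
        "below_counterfactual": bool(exposure <= scenario.counterfactual),
        "denominator_population": denom,
    }
    for key in ("low", "", "high"):
        suffix = f"_{key}" if key else ""
        adcol = f"ad{suffix}"
        yllcol = f"yll{suffix}"
        row[adcol] = float(impacts[adcol].sum())
        row[f"ad_rate{suffix}"] = rate_per_100k(row[adcol], denom)
        row[yllcol] = float(impacts[yllcol].sum())
        row[f"yll_rate{suffix}"] = rate_per_100k(row[yllcol], denom)
    row["lle_years_low"] = loss_of_life_expectancy(
        schedule, afm["low"], nax_closed=nax_closed, a0=a0
    )
    row["lle_years"] = loss_of_life_expectancy(
        schedule, afm["point"], nax_closed=nax_closed, a0=a0
    )
    row["lle_years_high"] = loss_of_life_expectancy(
        schedule, afm["high"], nax_closed=nax_closed, a0=a0
    )
    return row


@dataclass
class HIAResult:
    """District, province and study-region impact summaries plus raw impacts."""

    scenario: Scenario
    age_impacts: pd.DataFrame
    district: pd.DataFrame
    province: pd.DataFrame
    region: pd.DataFrame
    metadata: dict


def aggregate(
    impacts_by_unit: Mapping[str, pd.DataFrame],
    schedules: Mapping[str, MortalitySchedule],
    unit_to_province: Mapping[str, str],
    scenario: Scenario,
    exposures: Mapping[str, float],
    province_lle: str = "pooled",
    nax_closed: float = 2.5,
    a0: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roll district impacts up to provinces and the whole study region.

    Counts (AD, YLL) are summed; rates are recomputed from summed counts over
    summed denominators, never averaged.  Province/region LLE is recomputed
    from the pooled mortality schedule with the pooled per-band attributable
    fractions (``province_lle="pooled"``), or alternatively as the
    population-weighted mean of member LLEs (``"weighted"``).
    """
    orphans = [u for u in impacts_by_unit if u not in unit_to_province]
    if orphans:
        raise ValueError(f"districts without a province mapping: {orphans}")
    provinces: dict[str, list[str]] = {}
    for u, p in unit_to_province.items():
        if u in impacts_by_unit:
            provinces.setdefault(p, []).append(u)

    def _pooled_row(units: list[str], unit_id: str, level: str) -> dict:
        pooled = pool_schedules([schedules[u] for u in units], unit_id=unit_id)
        all_imp = pd.concat([impacts_by_unit[u] for u in units])
        summed = all_imp.groupby("age_group", sort=False)[
            ["af_low", "af", "af_high", "ad_low", "ad", "ad_high",
             "yll_low", "yll", "yll_high"]
        ].sum().reset_index()
        summed.insert(0, "unit_id", unit_id)
        pop_w = np.array([schedules[u].total_population for u in units])
        mean_exp = float(
            np.average([exposures[u] for u in units], weights=pop_w)
        )
        row = unit_summary(
            pooled, summed, scenario, mean_exp, level=level,
            nax_closed=nax_closed, a0=a0,
        )
        row["below_counterfactual"] = all(
            exposures[u] <= scenario.counterfactual for u in units
        )
        if province_lle == "weighted":
            for suffix in ("_low", "", "_high"):
                col = f"lle_years{suffix}"
                member = [
                    unit_summary(
                        schedules[u], impacts_by_unit[u], scenario,
                        exposures[u], nax_closed=nax_closed, a0=a0,
                    )[col]
                    for u in units
                ]
                row[col] = float(np.average(member, weights=pop_w))
        return row

    prov_rows = [
        _pooled_row(units, prov, "province")
        for prov, units in sorted(provinces.items())
    ]
    region_row = _pooled_row(sorted(impacts_by_unit), "study_region", "region")
    return pd.DataFrame(prov_rows), pd.DataFrame([region_row])


def run_hia(
    schedules: Mapping[str, MortalitySchedule],
    exposures: Mapping[str, float],
    scenario: Scenario,
    gemm: GEMMParameterSet | None = None,
    loglinear: LogLinearRisk | None = None,
    unit_to_province: Mapping[str, str] | None = None,
    province_lle: str = "pooled",
    nax_closed: float = 2.5,
    a0: float | None = None,
    **ci_kwargs,
) -> HIAResult:
    """Run the full pipeline over a set of units under one scenario."""
    missing = sorted(set(schedules) - set(exposures))
    if missing:
        raise ValueError(f"units without an exposure value: {missing}")
    if scenario.risk_model == "gemm" and gemm is None:
        gemm = GEMMParameterSet.default()

    impacts_by_unit: dict[str, pd.DataFrame] = {}
    district_rows = []
    for unit, sched in schedules.items():
        exp = exposures[unit]
        imp = attributable_deaths(
            sched, exp, scenario, gemm=gemm, loglinear=loglinear, **ci_kwargs
        )
        table = build_life_table(sched, nax_closed=nax_closed, a0=a0)
        imp = years_of_life_lost(imp, table)
        impacts_by_unit[unit] = imp
        district_rows.append(
            unit_summary(sched, imp, scenario, exp, nax_closed=nax_closed, a0=a0)
        )
    district = pd.DataFrame(district_rows)

    if unit_to_province is None:
        unit_to_province = {u: u for u in schedules}
    province, region = aggregate(
        impacts_by_unit, schedules, unit_to_province, scenario, exposures,
        province_lle=province_lle, nax_closed=nax_closed, a0=a0,
    )
    metadata = {
        "scenario": scenario.name,
        "counterfactual_ugm3": scenario.counterfactual,
        "risk_model": scenario.risk_model,
        "rate_denominator": scenario.rate_denominator,
        "province_lle": province_lle,
        "min_age": scenario.min_age,
    }
    return HIAResult(
        scenario=scenario,
        age_impacts=pd.concat(impacts_by_unit.values(), ignore_index=True),
        district=district,
        province=province,
        region=region,
        metadata=metadata,
    )


def run_comparison(
    schedules: Mapping[str, MortalitySchedule],
    exposures: Mapping[str, float],
    counterfactual: float = 5.0,
    gemm: GEMMParameterSet | None = None,
    loglinear: LogLinearRisk | None = None,
    gemm_denominator: str = "total-population",
) -> pd.DataFrame:
    """Paired AD rates per unit: AirQ+-style log-linear vs GEMM NCD+LRI.

    The two columns mirror how the two tools report: the log-linear model
    applies to adults 30+ and its rate is per 100,000 of that 30+ exposed
    population, while the GEMM rate uses the standard reporting denominator
    (total population by default).  The base populations of the two columns
    therefore differ; both are included in the output.
    """
    gemm_scn = Scenario(
        "compare-gemm", counterfactual, "gemm", rate_denominator=gemm_denominator
    )
    ll_scn = Scenario(
        "compare-loglinear", counterfactual, "log-linear",
        rate_denominator="adults-only",
    )
    rows = []
    for unit, sched in schedules.items():
        exp = exposures[unit]
        g_imp = attributable_deaths(sched, exp, gemm_scn, gemm=gemm)
        ll_imp = attributable_deaths(sched, exp, ll_scn, loglinear=loglinear)
        if gemm_denominator == "total-population":
            g_denom = sched.total_population
        else:
            g_denom = sched.restrict(GEMM_MIN_AGE).total_population
        ll_denom = sched.restrict(LOGLINEAR_MIN_AGE).total_population
        rows.append(
            {
                "unit_id": unit,
                "exposure": exp,
                "ad_loglinear": float(ll_imp["ad"].sum()),
                "pop_loglinear": ll_denom,
                "ad_rate_loglinear": rate_per_100k(
                    float(ll_imp["ad"].sum()), ll_denom
                ),
                "ad_gemm": float(g_imp["ad"].sum()),
                "pop_gemm": g_denom,
                "ad_rate_gemm": rate_per_100k(float(g_imp["ad"].sum()), g_denom),
            }
        )
    return pd.DataFrame(rows)


def exposure_summary(
    exposures: Mapping[str, float] | pd.Series,
    thresholds: Mapping[str, float] | None = None,
) -> dict:
    """Minimum/maximum exposure and per-unit threshold-exceedance ratios.

    Ratios (concentration / threshold) are reported to 2 decimal places per
    unit and named threshold, e.g. AQG=5 and QCVN=15 ug/m3.
    """
    ser = pd.Series(dict(exposures), dtype=float)
    if ser.empty:
        raise ValueError("exposure table is empty")
    if thresholds is None:
        thresholds = {"AQG": 5.0, "QCVN": 15.0}
    for name, t in thresholds.items():
        if t <= 0:
            raise ValueError(f"threshold {name!r} must be > 0 ug/m3, got {t}")
    ratios = pd.DataFrame(
        {
            f"ratio_{name}": (ser / t).round(2)
            for name, t in thresholds.items()
        }
    )
    ratios.insert(0, "concentration", ser)
    ratios.index.name = "unit_id"
    return {
        "min": float(ser.min()),
        "max": float(ser.max()),
        "argmin": str(ser.idxmin()),
        "argmax": str(ser.idxmax()),
        "ratios": ratios,
    }
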