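"""Synthetic demography and exposure generators.

The generators emit inputs with the statistical structure the assessment
assumes so the whole pipeline is exercisable without any external download:

* demography: per-district all-age (0-4 ... 85+) mortality schedules with an
  exponential-decay age pyramid and a Gompertz-Makeham hazard
  ``mu(x) = a*exp(b*x) + c`` scaled so the crude adult (25+) death rate hits
  a target drawn from the configured range (default 4.1-8.3 per 1,000, the
  range observed across the 11-province study region in 2019);
* exposure: a per-district grid of annual-mean PM2.5 cells built from seeded
  noise smoothed with an exponential spatial kernel, recentred so district
  means span the configured range (default 15.8-40.8 ug/m3).

Passing a province summary table (name, adult population, crude adult rate,
annual-mean PM2.5) calibrates the generators to published marginals while the
age structure stays synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .life_table import MortalitySchedule

__all__ = ["SyntheticConfig", "generate_demography", "generate_exposure", "generate_inputs"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study region; defaults emulate the 2019 study
    conditions (11 provinces, adult populations 0.29-5.8 M, crude 25+ rates
    4.1-8.3 per 1,000, annual PM2.5 15.8-40.8 ug/m3)."""

    n_provinces: int = 11
    districts_per_province: int = 3
    crude_rate_range: tuple[float, float] = (4.1, 8.3)   # per 1,000, ages 25+
    adult_pop_range: tuple[float, float] = (0.29e6, 5.8e6)  # province 25+ pop
    exposure_range: tuple[float, float] = (15.8, 40.8)   # ug/m3 district means
    gompertz_a: float = 3.5e-5    # baseline hazard level at age 0 (1/yr)
    gompertz_b: float = 0.095     # log-hazard age slope (1/yr)
    makeham_c: float = 5e-4       # age-independent hazard (1/yr)
    pyramid_decay: float = 0.008  # stable-population growth decay (1/yr of age)
    open_age: int = 85
    grid_size: int = 6            # cells per district side
    spatial_corr_length: float = 2.0  # cells
    cell_noise_sd: float = 3.0    # ug/m3 before smoothing
    district_jitter: float = 1.5  # ug/m3 spread of district means in a province
    deaths: str = "expected"      # "expected" (rounded) | "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crude_rate_range", "adult_pop_range", "exposure_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive non-empty range, got ({lo}, {hi})")
        if self.n_provinces < 1 or self.districts_per_province < 1:
            raise ValueError("need at least one province and district")
        if self.spatial_corr_length <= 0:
            raise ValueError(
                f"spatial_corr_length must be > 0 cells, got {self.spatial_corr_length}"
            )
        if self.deaths not in ("expected", "poisson"):
            raise ValueError(f"unknown deaths mode {self.deaths!r}")


def _age_bands(open_age: int) -> tuple[list[str], np.ndarray, np.ndarray]:
    starts = np.arange(0, open_age + 1, 5)
    labels = [f"{s}-{s+4}" for s in starts[:-1]] + [f"{open_age}+"]
    mids = starts + 2.5
    mids[-1] = open_age + 5.0  # effective midpoint of the open interval
    widths = np.full(len(starts), 5.0)
    widths[-1] = 10.0          # effective width of the open interval
    return labels, mids, widths


def _province_frame(config: SyntheticConfig, province_targets, rng) -> pd.DataFrame:
    if province_targets is not None:
        df = province_targets.copy()
        required = {"province", "population_25plus", "death_rate_25plus_per_1000"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"province table missing columns: {sorted(required - set(df.columns))}"
            )
        return df.reset_index(drop=True)
    lo, hi = config.adult_pop_range
    pops = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_provinces))
    rlo, rhi = config.crude_rate_range
    rates = rng.uniform(rlo, rhi, config.n_provinces)
    return pd.DataFrame(
        {
            "province": [f"P{i+1:02d}" for i in range(config.n_provinces)],
            "population_25plus": pops,
            "death_rate_25plus_per_1000": rates,
        }
    )


def generate_demography(
    config: SyntheticConfig,
    province_targets: pd.DataFrame | None = None,
) -> tuple[dict[str, MortalitySchedule], dict[str, str]]:
    """Per-district all-age mortality schedules plus the district->province map.

    Deaths are rounded expectations (deterministic) by default, or seeded
    Poisson draws with ``config.deaths="poisson"``.  Raises when the target
    crude rate is unattainable for the configured hazard shape (the scaling
    needed would push band-level rates above 0.95/yr).
    """
    rng = np.random.default_rng([config.seed, 1])
    # separate stream for death-count noise so Poisson mode does not perturb
    # the structural draws (pyramids, shares) of later districts
    rng_deaths = np.random.default_rng([config.seed, 3])
    provinces = _province_frame(config, province_targets, rng)
    labels, mids, widths = _age_bands(config.open_age)
    hazard = config.gompertz_a * np.exp(config.gompertz_b * mids) + config.makeham_c
    # stable-population pyramid: band share ~ survivorship of the unscaled
    # hazard times an exponential growth discount, so the old-age share
    # tapers realistically instead of following the growth term alone
    cum_hazard = np.concatenate([[0.0], np.cumsum(hazard[:-1] * 5.0)])
    survivorship = np.exp(-cum_hazard)
    pyramid = survivorship * np.exp(-config.pyramid_decay * mids) * widths
    pyramid /= pyramid.sum()
    adult = mids >= 25.0
    adult_share = pyramid[adult].sum()

    schedules: dict[str, MortalitySchedule] = {}
    mapping: dict[str, str] = {}
    for prow in provinces.itertuples():
        shares = rng.dirichlet(np.full(config.districts_per_province, 8.0))
        target_rate = prow.death_rate_25plus_per_1000 / 1000.0
        for j, share in enumerate(shares):
            district = f"{prow.province}-D{j+1}"
            adult_pop = float(prow.population_25plus) * share
            total_pop = adult_pop / adult_share
            pop = np.maximum(np.rint(total_pop * pyramid), 1.0)
            scale = target_rate * pop[adult].sum() / (pop[adult] * hazard[adult]).sum()
            rates = scale * hazard
            if rates.max() >= 0.95:
                max_rate = 0.95 / hazard.max() * (pop[adult] * hazard[adult]).sum() / pop[adult].sum()
                raise ValueError(
                    "target crude 25+ rate unattainable for the configured "
                    f"hazard shape; achievable range is (0, {max_rate * 1000:.2f}) "
                    "per 1,000"
                )
            expected = rates * pop
            if config.deaths == "poisson":
                deaths = rng_deaths.poisson(expected).astype(float)
            else:
                deaths = np.rint(expected)
            deaths[-1] = max(deaths[-1], 1.0)
            schedules[district] = MortalitySchedule(
                age_groups=tuple(labels),
                population=pop,
                deaths=deaths,
                unit_id=district,
            )
            mapping[district] = str(prow.province)
    return schedules, mapping


def _exponential_kernel(corr_length: float, radius: int) -> np.ndarray:
    offsets = np.arange(-radius, radius + 1)
    dist = np.hypot(offsets[:, None], offsets[None, :])
    kernel = np.exp(-dist / corr_length)
    return kernel / kernel.sum()


def generate_exposure(
    config: SyntheticConfig,
    province_targets: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Grid-cell PM2.5 table: cell_id, district_id, province_id, concentration.

    Province-level means are taken from the ``pm25_annual_mean`` column of
    the target table when supplied, otherwise spaced evenly across the
    configured exposure range (highest first).  Districts within a province
    are offset by at most ``district_jitter``; the within-district field is
    smoothed seeded noise recentred on the district mean.
    """
    rng = np.random.default_rng([config.seed, 2])
    provinces = _province_frame(
        config, province_targets, np.random.default_rng([config.seed, 1])
    )
    n_prov = len(provinces)
    if province_targets is not None and "pm25_annual_mean" in provinces.columns:
        base = provinces["pm25_annual_mean"].to_numpy(dtype=float)
    else:
        hi, lo = config.exposure_range[1], config.exposure_range[0]
        base = np.linspace(hi, lo, n_prov) if n_prov > 1 else np.array([(hi + lo) / 2])

    g = config.grid_size
    kernel = _exponential_kernel(config.spatial_corr_length, radius=g)
    n_d = config.districts_per_province
    offsets = (
        np.linspace(-1.0, 1.0, n_d) * config.district_jitter
        if n_d > 1
        else np.zeros(1)
    )
    rows = []
    for p, prow in enumerate(provinces.itertuples()):
        for j in range(n_d):
            district = f"{prow.province}-D{j+1}"
            target = max(base[p] + offsets[j], 0.1)
            noise = rng.normal(0.0, config.cell_noise_sd, size=(g, g))
            smooth = ndimage.convolve(noise, kernel, mode="wrap")
            fld = np.maximum(smooth - smooth.mean() + target, 0.0)
            for k, value in enumerate(fld.ravel()):
                rows.append(
                    {
                        "cell_id": f"{district}-C{k:03d}",
                        "district_id": district,
                        "province_id": str(prow.province),
                        "concentration": float(value),
                        "weight": 1.0,
                    }
                )
    return pd.DataFrame(rows)


def generate_inputs(
    config: SyntheticConfig,
    province_targets: pd.DataFrame | None = None,
) -> tuple[dict[str, MortalitySchedule], dict[str, str], pd.DataFrame]:
    """Demography, district->province map and exposure cells in one call."""
    schedules, mapping = generate_demography(config, province_targets)
    cells = generate_exposure(config, province_targets)
    return schedules, mapping, cells
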