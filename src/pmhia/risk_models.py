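"""Exposure-response functions for long-term PM2.5 mortality.

Two risk models are provided:

* the Global Exposure Mortality Model (GEMM) hazard ratio for the combined
  non-communicable disease + lower respiratory infection (NCD+LRI) outcome,
  a supra-linear function of annual-mean PM2.5 with age-specific scale
  parameters, and
* the single-parameter log-linear relative risk conventionally used by
  AirQ+-style assessments (a constant relative risk per 10 ug/m3 of excess
  exposure).

Both feed the standard counterfactual population-attributable fraction
``AF = 1 - HR(c_cf) / HR(c_obs)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GEMMParams",
    "GEMMParameterSet",
    "LogLinearRisk",
    "ADULT_AGE_GROUPS",
    "gemm_hazard_ratio",
    "loglinear_rr",
    "attributable_fraction",
]

#: 5-year adult age bands covered by the packaged GEMM NCD+LRI parameters.
ADULT_AGE_GROUPS: tuple[str, ...] = (
    "25-29", "30-34", "35-39", "40-44", "45-49", "50-54", "55-59",
    "60-64", "65-69", "70-74", "75-79", "80-84", "85+",
)

#: Internal GEMM counterfactual (ug/m3): the lowest exposure observed in the
#: pooled cohorts; concentrations are measured as z = max(0, C - GEMM_ZCF).
GEMM_ZCF = 2.4


@dataclass(frozen=True)
class GEMMParams:
    """GEMM hazard-function parameters for one 5-year adult age group.

    ``theta`` scales the log hazard; ``alpha`` (ug/m3) sets the curvature of
    ``log(1 + z/alpha)``; ``mu`` and ``nu`` (ug/m3) locate and widen the
    logistic weight; ``zcf`` is the internal counterfactual offset.
    """

    age_group: str
    theta: float
    theta_se: float
    alpha: float
    mu: float
    nu: float
    zcf: float = GEMM_ZCF

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha} (ug/m3)")
        if self.nu <= 0:
            raise ValueError(f"nu must be > 0, got {self.nu} (ug/m3)")
        if self.theta_se < 0:
            raise ValueError(f"theta_se must be >= 0, got {self.theta_se}")
        if self.zcf < 0:
            raise ValueError(f"zcf must be >= 0, got {self.zcf} (ug/m3)")


class GEMMParameterSet(Mapping[str, GEMMParams]):
    """Age-group-indexed GEMM parameter table (one row per adult band).

    Behaves as a mapping from age-group label (``"25-29"`` ... ``"85+"``) to
    :class:`GEMMParams`.  The packaged NCD+LRI table is loaded by
    :meth:`default`; an alternative file with the same columns can be loaded
    with :meth:`from_csv`.
    """

    def __init__(self, rows: Mapping[str, GEMMParams]):
        missing = [g for g in ADULT_AGE_GROUPS if g not in rows]
        if missing:
            raise ValueError(
                f"parameter set has gaps in the adult age groups: {missing}"
            )
        self._rows = dict(rows)

    def __getitem__(self, label: str) -> GEMMParams:
        try:
            return self._rows[label]
        except KeyError:
            raise KeyError(
                f"unknown age group {label!r}; valid groups: "
                f"{sorted(self._rows)}"
            ) from None

    def __iter__(self):
        return iter(self._rows)

    def __len__(self) -> int:
        return len(self._rows)

    @classmethod
    def from_csv(cls, path, zcf: float = GEMM_ZCF) -> "GEMMParameterSet":
        df = pd.read_csv(path, comment="#")
        required = {"age_group", "theta", "theta_se", "alpha", "mu", "nu"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"GEMM parameter file missing columns: {sorted(required - set(df.columns))}"
            )
        rows = {
            str(r.age_group): GEMMParams(
                age_group=str(r.age_group), theta=float(r.theta),
                theta_se=float(r.theta_se), alpha=float(r.alpha),
                mu=float(r.mu), nu=float(r.nu), zcf=zcf,
            )
            for r in df.itertuples()
        }
        return cls(rows)

    @classmethod
    def default(cls) -> "GEMMParameterSet":
        """The packaged GEMM NCD+LRI age-specific parameter table."""
        ref = resources.files("pmhia.data").joinpath("gemm_ncd_lri.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


@dataclass(frozen=True)
class LogLinearRisk:
    """Log-linear relative risk per 10 ug/m3 of PM2.5 above a counterfactual.

    Default 1.062 (95% CI 1.040-1.083), the all-natural-cause adult estimate
    from the Hoek et al. meta-analysis used by AirQ+'s long-term mortality
    option.
    """

    rr_per_10: float = 1.062
    ci_low_per_10: float = 1.040
    ci_high_per_10: float = 1.083

    def __post_init__(self) -> None:
        if self.rr_per_10 <= 0:
            raise ValueError(f"rr_per_10 must be > 0, got {self.rr_per_10}")
        if not (self.ci_low_per_10 <= self.rr_per_10 <= self.ci_high_per_10):
            raise ValueError(
                "relative-risk interval must bracket the point estimate: "
                f"{self.ci_low_per_10} <= {self.rr_per_10} <= {self.ci_high_per_10}"
            )


def _logistic_weight(z: np.ndarray | float, mu: float, nu: float):
    return 1.0 / (1.0 + np.exp(-(np.asarray(z, dtype=float) - mu) / nu))


def gemm_hazard_ratio(
    concentration: float | np.ndarray,
    params: GEMMParams,
    theta_override: float | None = None,
) -> float | np.ndarray:
    """GEMM hazard ratio at an annual-mean PM2.5 concentration (ug/m3).

    ``HR(z) = exp(theta * log(1 + z/alpha) * omega(z))`` with
    ``z = max(0, concentration - zcf)`` and logistic weight
    ``omega(z) = 1 / (1 + exp(-(z - mu)/nu))``.

    ``theta_override`` substitutes theta, which is how interval bounds
    (``theta +/- 1.96*SE``) are evaluated end to end.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        bad = c[c < 0] if c.ndim else c
        raise ValueError(
            f"PM2.5 concentration must be >= 0 ug/m3, got {bad} ug/m3"
        )
    theta = params.theta if theta_override is None else theta_override
    z = np.maximum(0.0, c - params.zcf)
    log_term = np.log1p(z / params.alpha)
    hr = np.exp(theta * log_term * _logistic_weight(z, params.mu, params.nu))
    return float(hr) if np.isscalar(concentration) else hr


def loglinear_rr(
    c_obs: float, c_cf: float, risk: LogLinearRisk | None = None,
    rr_per_10: float | None = None,
) -> float:
    """Relative risk for exposure ``c_obs`` vs counterfactual ``c_cf``.

    ``RR = rr_per_10 ** ((c_obs - c_cf)/10)``, with the excess exposure
    floored at zero so that exposures at or below the counterfactual carry
    no excess risk.
    """
    if risk is None:
        risk = LogLinearRisk()
    if rr_per_10 is None:
        rr_per_10 = risk.rr_per_10
    if rr_per_10 <= 0:
        raise ValueError(f"rr_per_10 must be > 0, got {rr_per_10}")
    if c_obs < 0:
        raise ValueError(f"observed PM2.5 must be >= 0 ug/m3, got {c_obs}")
    if c_cf < 0:
        raise ValueError(f"counterfactual PM2.5 must be >= 0 ug/m3, got {c_cf}")
    excess = max(0.0, c_obs - c_cf)
    return float(rr_per_10 ** (excess / 10.0))


def attributable_fraction(hr_obs: float, hr_cf: float) -> float:
    """Counterfactual population-attributable fraction ``1 - hr_cf/hr_obs``.

    Clamped to 0 when the observed hazard does not exceed the counterfactual
    hazard (no negative burden is attributed).
    """
    if hr_obs <= 0 or hr_cf <= 0:
        raise ValueError(
            f"hazard ratios must be > 0, got hr_obs={hr_obs}, hr_cf={hr_cf}"
        )
    if hr_obs <= hr_cf:
        return 0.0
    return 1.0 - hr_cf / hr_obs
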