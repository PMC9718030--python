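"""Abridged (5-year) period life tables.

A :class:`MortalitySchedule` holds population and non-injury death counts on
contiguous 5-year age bands with an open terminal band (default 85+).
:func:`build_life_table` converts the central death rates nMx into the usual
abridged life-table columns (nqx, lx, ndx, nLx, Tx, ex) with the standard
actuarial approximation ``nqx = n*nMx / (1 + (n - nax)*nMx)`` and a
constant-hazard open interval (``nLx = lx/nMx``).  Remaining life expectancy
ex weights attributable deaths into years of life lost, and the difference in
e0 between an observed and a counterfactual schedule is the loss of life
expectancy at birth.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MortalitySchedule",
    "LifeTable",
    "build_life_table",
    "remaining_life_expectancy",
    "perturb_schedule",
    "pool_schedules",
    "parse_age_group",
]

logger = logging.getLogger(__name__)

_BAND_RE = re.compile(r"^(\d+)-(\d+)$")
_OPEN_RE = re.compile(r"^(\d+)\+$")


def parse_age_group(label: str) -> tuple[int, float]:
    """Return (start, end) in years for a band label; end is inf for "85+"."""
    m = _BAND_RE.match(label)
    if m:
        start, last = int(m.group(1)), int(m.group(2))
        if last < start:
            raise ValueError(f"malformed age band {label!r}")
        return start, float(last + 1)
    m = _OPEN_RE.match(label)
    if m:
        return int(m.group(1)), float("inf")
    raise ValueError(f"unrecognised age-group label {label!r}")


@dataclass(frozen=True)
class MortalitySchedule:
    """Population and annual non-injury deaths on contiguous 5-year bands."""

    age_groups: tuple[str, ...]
    population: np.ndarray
    deaths: np.ndarray
    unit_id: str = ""

    def __post_init__(self) -> None:
        pop = np.asarray(self.population, dtype=float)
        dth = np.asarray(self.deaths, dtype=float)
        object.__setattr__(self, "population", pop)
        object.__setattr__(self, "deaths", dth)
        n = len(self.age_groups)
        if pop.shape != (n,) or dth.shape != (n,):
            raise ValueError("age_groups, population and deaths must align")
        if n == 0:
            raise ValueError("schedule has no age bands")
        bounds = [parse_age_group(g) for g in self.age_groups]
        starts = [b[0] for b in bounds]
        ends = [b[1] for b in bounds]
        if any(np.isinf(e) for e in ends[:-1]) or not np.isinf(ends[-1]):
            raise ValueError(
                "exactly one open-ended band is required and it must be last; "
                f"got {self.age_groups}"
            )
        for i in range(1, n):
            if starts[i] != ends[i - 1]:
                raise ValueError(
                    f"age bands must be contiguous and ascending; gap between "
                    f"{self.age_groups[i-1]!r} and {self.age_groups[i]!r}"
                )
        if np.any(pop <= 0):
            bad = [self.age_groups[i] for i in np.flatnonzero(pop <= 0)]
            raise ValueError(f"population must be > 0 in every band; zero/negative in {bad}")
        if np.any(dth < 0):
            bad = [self.age_groups[i] for i in np.flatnonzero(dth < 0)]
            raise ValueError(f"negative death counts in bands {bad}")
        if dth[-1] <= 0:
            raise ValueError(
                f"terminal band {self.age_groups[-1]!r} must have a positive death rate"
            )

    @property
    def rates(self) -> np.ndarray:
        """Central death rates nMx (deaths per person-year) by band."""
        return self.deaths / self.population

    @property
    def starts(self) -> np.ndarray:
        return np.array([parse_age_group(g)[0] for g in self.age_groups])

    @property
    def widths(self) -> np.ndarray:
        """Band widths in years; inf for the open terminal band."""
        bounds = [parse_age_group(g) for g in self.age_groups]
        return np.array([e - s for s, e in bounds])

    @property
    def total_population(self) -> float:
        return float(self.population.sum())

    def restrict(self, min_age: int) -> "MortalitySchedule":
        """Keep only bands starting at or above ``min_age`` (e.g. 25 or 30)."""
        keep = self.starts >= min_age
        if not keep.any():
            raise ValueError(f"no bands at or above age {min_age}")
        return MortalitySchedule(
            age_groups=tuple(np.array(self.age_groups)[keep]),
            population=self.population[keep],
            deaths=self.deaths[keep],
            unit_id=self.unit_id,
        )

    def crude_rate(self, min_age: int = 0) -> float:
        """Crude death rate (per person-year) at or above ``min_age``."""
        keep = self.starts >= min_age
        return float(self.deaths[keep].sum() / self.population[keep].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": self.unit_id,
                "age_group": list(self.age_groups),
                "population": self.population,
                "deaths_noninjury": self.deaths,
            }
        )


class LifeTable:
    """Abridged life table; one row per age band, radix 100,000."""

    RADIX = 100_000.0

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame
        if not (np.diff(frame["lx"].to_numpy()) <= 1e-9).all():
            raise ValueError("survivorship lx must be non-increasing")

    @property
    def e0(self) -> float:
        """Life expectancy at birth (ex of the first band)."""
        return float(self.frame["ex"].iloc[0])

    def ex(self, age_group: str) -> float:
        sel = self.frame.loc[self.frame["age_group"] == age_group, "ex"]
        if sel.empty:
            raise KeyError(
                f"age group {age_group!r} not in life table; valid groups: "
                f"{list(self.frame['age_group'])}"
            )
        return float(sel.iloc[0])


def build_life_table(
    schedule: MortalitySchedule,
    nax_closed: float = 2.5,
    a0: float | None = None,
) -> LifeTable:
    """Build an abridged life table from a mortality schedule.

    ``nax_closed`` is the average number of years lived in a closed interval
    by those dying in it (default n/2 = 2.5 years).  ``a0`` optionally
    overrides nax for the first (0-4) band, e.g. a Coale-Demeny style 0.3*n
    when infant mortality is concentrated early; the sex-aggregated 5-year
    default keeps n/2.  The open interval assumes a constant hazard:
    nqx = 1, nLx = lx/nMx, so its ex equals 1/nMx.
    """
    m = schedule.rates
    n = schedule.widths
    k = len(m)
    nax = np.full(k, nax_closed)
    if a0 is not None and parse_age_group(schedule.age_groups[0])[0] == 0:
        nax[0] = a0

    nqx = np.empty(k)
    closed = slice(0, k - 1)
    nqx[closed] = n[closed] * m[closed] / (1.0 + (n[closed] - nax[closed]) * m[closed])
    if np.any(nqx[closed] > 1.0):
        bad = [schedule.age_groups[i] for i in np.flatnonzero(nqx[:-1] > 1.0)]
        logger.warning("death probability nqx > 1 clamped to 1 in bands %s", bad)
        nqx[closed] = np.minimum(nqx[closed], 1.0)
    nqx[-1] = 1.0
    nax[-1] = np.nan

    lx = np.empty(k)
    lx[0] = LifeTable.RADIX
    for i in range(1, k):
        lx[i] = lx[i - 1] * (1.0 - nqx[i - 1])
    ndx = np.empty(k)
    ndx[:-1] = lx[:-1] * nqx[:-1]
    ndx[-1] = lx[-1]

    nLx = np.empty(k)
    nLx[:-1] = n[:-1] * (lx[:-1] - ndx[:-1]) + nax[:-1] * ndx[:-1]
    nLx[-1] = lx[-1] / m[-1] if lx[-1] > 0 else 0.0

    Tx = np.cumsum(nLx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)

    frame = pd.DataFrame(
        {
            "age_group": list(schedule.age_groups),
            "nMx": m,
            "nax": nax,
            "nqx": nqx,
            "lx": lx,
            "ndx": ndx,
            "nLx": nLx,
            "Tx": Tx,
            "ex": ex,
        }
    )
    return LifeTable(frame)


def remaining_life_expectancy(table: LifeTable, age_group: str) -> float:
    """ex (years) of the band with the given label."""
    return table.ex(age_group)


def perturb_schedule(
    schedule: MortalitySchedule, af_by_band: Mapping[str, float]
) -> MortalitySchedule:
    """Remove an attributable fraction of deaths from each adult band.

    Returns the counterfactual "without PM2.5" schedule in which band ``a``
    has deaths (hence rate) scaled by ``1 - af_a``.  Bands not listed keep
    their observed deaths; fractions are only accepted for bands starting at
    25 or later (childhood mortality carries no attributable fraction here).
    """
    af = np.zeros(len(schedule.age_groups))
    starts = schedule.starts
    index = {g: i for i, g in enumerate(schedule.age_groups)}
    for band, f in af_by_band.items():
        if band not in index:
            raise KeyError(
                f"age group {band!r} not in schedule; valid: {list(index)}"
            )
        if not (0.0 <= f < 1.0):
            raise ValueError(
                f"attributable fraction for {band!r} must be in [0, 1), got {f}"
            )
        if starts[index[band]] < 25 and f != 0.0:
            raise ValueError(
                f"attributable fractions apply to adult (25+) bands only, got {band!r}"
            )
        af[index[band]] = f
    return MortalitySchedule(
        age_groups=schedule.age_groups,
        population=schedule.population,
        deaths=schedule.deaths * (1.0 - af),
        unit_id=schedule.unit_id,
    )


def pool_schedules(
    schedules: Sequence[MortalitySchedule], unit_id: str = "pooled"
) -> MortalitySchedule:
    """Sum populations and deaths band-wise across units (same band layout)."""
    if not schedules:
        raise ValueError("no schedules to pool")
    groups = schedules[0].age_groups
    for s in schedules[1:]:
        if s.age_groups != groups:
            raise ValueError(
                f"cannot pool schedules with differing bands: {s.unit_id!r}"
            )
    return MortalitySchedule(
        age_groups=groups,
        population=np.sum([s.population for s in schedules], axis=0),
        deaths=np.sum([s.deaths for s in schedules], axis=0),
        unit_id=unit_id,
    )
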