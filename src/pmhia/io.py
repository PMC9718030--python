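"""CSV readers/writers, YAML config and run provenance.

All interchange files are UTF-8 comma-separated with a mandatory header row
and dot decimals; unit identifiers are opaque strings.  Writers are
deterministic for identical inputs (stable column order and rounding).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .life_table import MortalitySchedule, build_life_table

__all__ = [
    "load_demography",
    "write_demography",
    "load_exposure_cells",
    "load_district_exposure",
    "write_district_exposure",
    "write_impact_tables",
    "write_life_table",
    "load_config",
    "DEFAULT_CONFIG",
    "RunManifest",
]

DEMOGRAPHY_COLUMNS = ["unit_id", "age_group", "population", "deaths_noninjury"]

#: Rounding used for report tables: deaths to integers, rates and
#: person-years and LLE to one decimal; internal computation is full
#: precision.
REPORT_ROUNDING = {"ad": 0, "ad_rate": 1, "yll": 1, "yll_rate": 1, "lle_years": 1}

DEFAULT_CONFIG: dict = {
    "scenarios": [
        {"name": "AQG", "counterfactual": 5.0, "risk_model": "gemm"},
        {"name": "QCVN", "counterfactual": 15.0, "risk_model": "gemm"},
    ],
    "rate_denominator": "total-population",
    "rr_per_10": 1.062,
    "rr_ci_per_10": [1.040, 1.083],
    "open_age": 85,
    "nax_closed": 2.5,
    "a0": None,
    "province_lle": "pooled",
    "ci_method": "delta",
    "rounding": True,
    "seed": 0,
}


def load_demography(path) -> dict[str, MortalitySchedule]:
    """Read the demography CSV into one all-age schedule per unit.

    Expected columns: unit_id, age_group, population, deaths_noninjury and an
    optional boolean ``injury_excluded`` flag that, when present, must be
    true on every row (deaths must already exclude injuries upstream).
    Raises with row-level diagnostics for schema problems, gaps or negative
    counts.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in DEMOGRAPHY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "injury_excluded" in df.columns:
        bad = df.loc[~df["injury_excluded"].astype(bool)]
        if not bad.empty:
            raise ValueError(
                f"{path}: rows {bad.index.tolist()} carry injury-inclusive "
                "death counts (injury_excluded is false)"
            )
    neg = df.loc[(df["population"] <= 0) | (df["deaths_noninjury"] < 0)]
    if not neg.empty:
        raise ValueError(
            f"{path}: non-positive population or negative deaths at rows "
            f"{neg.index.tolist()}"
        )
    schedules: dict[str, MortalitySchedule] = {}
    for unit, grp in df.groupby("unit_id", sort=True):
        try:
            schedules[str(unit)] = MortalitySchedule(
                age_groups=tuple(grp["age_group"].astype(str)),
                population=grp["population"].to_numpy(dtype=float),
                deaths=grp["deaths_noninjury"].to_numpy(dtype=float),
                unit_id=str(unit),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: unit {unit!r}: {exc}") from exc
    if not schedules:
        raise ValueError(f"{path}: no demography rows")
    return schedules


def write_demography(schedules: dict[str, MortalitySchedule], path) -> None:
    frames = [schedules[u].to_frame() for u in sorted(schedules)]
    out = pd.concat(frames, ignore_index=True)
    out["injury_excluded"] = True
    out.to_csv(path, index=False)


def load_exposure_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"cell_id", "district_id", "concentration"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def load_district_exposure(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"district_id", "annual_mean"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["annual_mean"] < 0).any():
        raise ValueError(f"{path}: negative annual-mean concentrations")
    return df


def write_district_exposure(district_exposure: pd.DataFrame, path) -> None:
    district_exposure.to_csv(path, index=False)


def _round_impacts(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for base, ndigits in REPORT_ROUNDING.items():
        for col in (f"{base}_low", base, f"{base}_high"):
            if col in out.columns:
                out[col] = out[col].round(ndigits)
                if ndigits == 0:
                    out[col] = out[col].astype("Int64")
    return out


def write_impact_tables(summaries: pd.DataFrame, path, rounding: bool = True) -> None:
    """Write an impact-summary frame as a report CSV.

    Columns: unit, AD (low/point/high), AD rate per 100,000, YLL, YLL rate,
    LLE in years, each with its 95% interval, plus the denominator
    population.  Incomplete interval triplets are rejected.
    """
    cols = [
        "unit_id", "level", "scenario", "exposure", "below_counterfactual",
        "denominator_population",
        "ad", "ad_low", "ad_high",
        "ad_rate", "ad_rate_low", "ad_rate_high",
        "yll", "yll_low", "yll_high",
        "yll_rate", "yll_rate_low", "yll_rate_high",
        "lle_years", "lle_years_low", "lle_years_high",
    ]
    if summaries.empty:
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return
    missing = [c for c in cols if c not in summaries.columns]
    if missing:
        raise ValueError(f"impact summary missing columns {missing}")
    out = summaries[cols].sort_values(["level", "unit_id"]).reset_index(drop=True)
    if rounding:
        out = _round_impacts(out)
    out.to_csv(path, index=False)


def write_life_table(table_frame: pd.DataFrame, path) -> None:
    table_frame.to_csv(path, index=False)


def load_config(path=None) -> dict:
    """Merge a YAML config file over the package defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = sorted(set(user) - set(cfg))
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        cfg.update(user)
    return cfg


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance block written next to every output set."""

    config: dict
    inputs: dict = field(default_factory=dict)   # path -> sha256
    outputs: list = field(default_factory=list)
    parameter_file_version: str = "gemm_ncd_lri.csv v1"
    package_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def add_input(self, path) -> None:
        self.inputs[str(path)] = sha256_of(path)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
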