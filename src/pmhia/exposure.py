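"""Zonal aggregation of a gridded annual-mean PM2.5 surface to districts.

The canonical interchange is a flat CSV of grid cells (cell_id, district_id,
concentration, optional weight); each district's exposure is the (optionally
weighted) mean of its member cells.  Monthly cell values can first be
collapsed to annual means.
"""

from __future__ import annotations

import calendar

import numpy as np
import pandas as pd

__all__ = ["aggregate_to_district", "monthly_to_annual"]

# non-leap calendar (the reference year, 2019, is non-leap)
_DAYS_IN_MONTH = np.array([calendar.monthrange(2019, m)[1] for m in range(1, 13)])


def aggregate_to_district(
    cells: pd.DataFrame, weighting: str = "uniform"
) -> pd.DataFrame:
    """One annual-mean concentration per district from member grid cells.

    ``weighting="uniform"`` takes the arithmetic mean of cell values;
    ``"weighted"`` uses the ``weight`` column (area fraction or population).
    The result carries district_id, annual_mean, n_cells and, when present,
    the province_id of the member cells.
    """
    required = {"district_id", "concentration"}
    if not required.issubset(cells.columns):
        raise ValueError(
            f"cell table missing columns: {sorted(required - set(cells.columns))}"
        )
    if cells.empty:
        raise ValueError("cell table is empty")
    if (cells["concentration"] < 0).any():
        bad = cells.loc[cells["concentration"] < 0, "cell_id"].tolist()[:5]
        raise ValueError(f"negative concentrations in cells {bad}")
    if weighting == "uniform":
        w = pd.Series(1.0, index=cells.index)
    elif weighting == "weighted":
        if "weight" not in cells.columns:
            raise ValueError('weighting="weighted" requires a weight column')
        w = cells["weight"].astype(float)
        if (w < 0).any():
            raise ValueError("cell weights must be >= 0")
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    rows = []
    for district, grp in cells.groupby("district_id", sort=True):
        wg = w.loc[grp.index]
        if wg.sum() <= 0:
            raise ValueError(f"district {district!r} has zero total cell weight")
        mean = float(np.average(grp["concentration"], weights=wg))
        row = {
            "district_id": district,
            "annual_mean": mean,
            "n_cells": len(grp),
        }
        if "province_id" in grp.columns:
            provs = grp["province_id"].unique()
            if len(provs) > 1:
                raise ValueError(
                    f"district {district!r} cells map to several provinces: {provs}"
                )
            row["province_id"] = provs[0]
        rows.append(row)
    return pd.DataFrame(rows)


def monthly_to_annual(
    monthly: pd.DataFrame,
    day_weighted: bool = False,
    max_missing: int = 0,
) -> pd.DataFrame:
    """Collapse 12 monthly means per cell to one annual mean.

    Expects a long frame with cell_id, month (1-12) and concentration.
    Default is the unweighted mean of the 12 monthly values; with
    ``day_weighted`` the months are weighted by their calendar-day counts.
    Cells missing more than ``max_missing`` months are rejected.
    """
    required = {"cell_id", "month", "concentration"}
    if not required.issubset(monthly.columns):
        raise ValueError(
            f"monthly table missing columns: {sorted(required - set(monthly.columns))}"
        )
    bad_month = ~monthly["month"].isin(range(1, 13))
    if bad_month.any():
        raise ValueError(
            f"month values outside 1-12: {sorted(monthly.loc[bad_month, 'month'].unique())}"
        )
    rows = []
    for cell, grp in monthly.groupby("cell_id", sort=True):
        months = grp["month"].to_numpy()
        if len(np.unique(months)) != len(months):
            raise ValueError(f"cell {cell!r} has duplicated months")
        n_missing = 12 - len(months)
        if n_missing > max_missing:
            raise ValueError(
                f"cell {cell!r} is missing {n_missing} months "
                f"(tolerance {max_missing})"
            )
        conc = grp["concentration"].to_numpy(dtype=float)
        if day_weighted:
            w = _DAYS_IN_MONTH[months - 1]
            annual = float(np.average(conc, weights=w))
        else:
            annual = float(conc.mean())
        rows.append({"cell_id": cell, "annual_mean": annual, "n_months": len(months)})
    return pd.DataFrame(rows)
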