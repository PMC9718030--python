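"""Packaged reference tables for the 2019 Vietnamese study region."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_province_summary", "VIETNAM_TOTAL_POPULATION_2019"]

#: Total population of Vietnam in the 2019 GSO census.
VIETNAM_TOTAL_POPULATION_2019 = 96_208_984


def load_province_summary() -> pd.DataFrame:
    """Published 2019 marginals for the 11 study-region provinces.

    Columns: province, pm25_annual_mean (ug/m3), population_25plus, and
    death_rate_25plus_per_1000 (crude, non-injury causes).
    """
    ref = resources.files("pmhia.data").joinpath("vietnam_provinces_2019.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")
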