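"""Independent life-table oracle: discrete-time cohort microsimulation.

Simulates a closed cohort through yearly Bernoulli survival draws with the
band's central death rate converted to a yearly death probability
q = 1 - exp(-m).  Decedents are credited half a year in their year of death.
Deliberately shares no code with pmhia.life_table: it estimates e0/ex by
counting person-years in a simulated population rather than by the abridged
life-table identities.
"""

from __future__ import annotations

import numpy as np

MAX_AGE = 5000  # safety cap; the open interval runs until cohort extinction


def cohort_life_expectancies(
    band_starts: np.ndarray,
    rates: np.ndarray,
    n: int = 1_000_000,
    seed: int = 0,
) -> dict[int, float]:
    """Remaining life expectancy at each band start (key 0 gives e0).

    ``band_starts`` are the starting ages of contiguous bands, the last band
    being open-ended; ``rates`` are the matching central death rates.
    """
    rng = np.random.default_rng(seed)
    band_starts = np.asarray(band_starts)
    yearly_m = np.empty(MAX_AGE)
    for i, start in enumerate(band_starts):
        end = band_starts[i + 1] if i + 1 < len(band_starts) else MAX_AGE
        yearly_m[start:end] = rates[i]
    q = 1.0 - np.exp(-yearly_m)

    alive = n
    alive_at_age = np.zeros(MAX_AGE + 1, dtype=np.int64)
    person_years = np.zeros(MAX_AGE)
    for age in range(MAX_AGE):
        alive_at_age[age] = alive
        if alive == 0:
            break  # cohort extinct
        deaths = rng.binomial(alive, q[age])
        person_years[age] = (alive - deaths) + 0.5 * deaths
        alive -= deaths
    else:
        raise RuntimeError("cohort not extinct by the safety cap")

    out: dict[int, float] = {}
    for start in band_starts:
        at_risk = alive_at_age[start]
        if at_risk > 0:
            out[int(start)] = float(person_years[start:].sum() / at_risk)
    return out
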