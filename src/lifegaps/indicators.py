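"""Individual mortality indicators: cohort LEB attribution, YPLLG, YPLL.

YPLLG (years of potential life lost or gained) is the signed difference
between an individual's age at death and the cohort life expectancy at
birth (LEB) attributed from their birth year and gender. Positive values
mean the person outlived their cohort expectation. YPLL is the classical
one-sided indicator relative to a fixed cutoff (75 years by default):
years not lived before the cutoff, never negative.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

YPLL_CUTOFF_YEARS = 75.0


class LifeTableLookupError(KeyError):
    """A (birth_year, gender) key requested from a life table is absent."""


class LifeTable:
    """Cohort life expectancy at birth, keyed by (birth_year, gender).

    Lookups are total over the table's keys: a missing key raises
    :class:`LifeTableLookupError` rather than interpolating, since the
    source tables span every birth year of interest and a gap signals
    malformed input.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"birth_year", "gender", "leb_years"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"life table missing columns: {sorted(missing)}")
        leb = table["leb_years"].to_numpy(dtype=float)
        if not np.all(np.isfinite(leb)) or np.any(leb <= 0):
            raise ValueError("leb_years must be finite and positive")
        self._frame = table.reset_index(drop=True)
        self._map = {
            (int(y), str(g)): float(e)
            for y, g, e in zip(table["birth_year"], table["gender"], table["leb_years"])
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __contains__(self, key: tuple[int, str]) -> bool:
        return (int(key[0]), str(key[1])) in self._map

    def lookup(self, birth_year, gender) -> np.ndarray:
        """Vectorized LEB lookup; scalar inputs give a 0-d result element."""
        years = np.atleast_1d(np.asarray(birth_year, dtype=int))
        genders = np.atleast_1d(np.asarray(gender, dtype=object))
        if years.shape != genders.shape:
            raise ValueError("birth_year and gender must have matching shapes")
        out = np.empty(years.shape, dtype=float)
        for i, (y, g) in enumerate(zip(years, genders)):
            key = (int(y), str(g))
            if key not in self._map:
                raise LifeTableLookupError(f"no life-table entry for (birth_year={y}, gender={g})")
            out[i] = self._map[key]
        if np.isscalar(birth_year) or (np.ndim(birth_year) == 0):
            return out[0]
        return out


def age_at_death(birth_date, death_date):
    """Fractional age at death in years: exact day count / 365.25.

    Accepts scalars or array-likes of dates. Raises if any death precedes
    the corresponding birth.
    """
    birth = pd.to_datetime(birth_date)
    death = pd.to_datetime(death_date)
    delta_days = (death - birth) / pd.Timedelta(days=1)
    arr = np.atleast_1d(np.asarray(delta_days, dtype=float))
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("death_date precedes birth_date")
    age = arr / DAYS_PER_YEAR
    if np.ndim(delta_days) == 0:
        return float(age[0])
    return age


def attribute_leb(records: pd.DataFrame, table: LifeTable) -> np.ndarray:
    """Attribute cohort LEB to each record from its birth year and gender."""
    birth_years = pd.to_datetime(records["birth_date"]).dt.year.to_numpy()
    return np.asarray(table.lookup(birth_years, records["gender"].to_numpy()), dtype=float)


def compute_yplg(age_at_death_years, leb_years):
    """Signed years of potential life lost (<0) or gained (>0)."""
    return np.asarray(age_at_death_years, dtype=float) - np.asarray(leb_years, dtype=float)


def compute_ypll(age_at_death_years, cutoff: float = YPLL_CUTOFF_YEARS):
    """Years of potential life lost relative to a fixed cutoff; never negative."""
    age = np.asarray(age_at_death_years, dtype=float)
    return np.maximum(0.0, cutoff - age)


def attach_indicators(
    records: pd.DataFrame, table: LifeTable, ypll_cutoff: float = YPLL_CUTOFF_YEARS
) -> pd.DataFrame:
    """Append age_at_death, leb, yplg and ypll columns to a record table."""
    out = records.copy()
    out["age_at_death"] = age_at_death(out["birth_date"], out["death_date"])
    out["leb"] = attribute_leb(out, table)
    out["yplg"] = compute_yplg(out["age_at_death"], out["leb"])
    out["ypll"] = compute_ypll(out["age_at_death"], cutoff=ypll_cutoff)
    return out
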