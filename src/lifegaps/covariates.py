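"""Neighborhood covariates: grouped-data median age and covariate attachment.

Neighborhood (statistical-subsector) characteristics arrive as a yearly
panel: median household income and resident counts by 5-year age group
with a final open class folded to [100, 105) — the derivation assumes
nobody lives past 105 so that all classes have equal width. The median
population age is estimated with the classical grouped-data formula.
Covariates are attached to individuals at their subsector for the year of
death; when that cell is absent from the panel, the nearest subsector
(centroid Euclidean distance, ties broken by smallest id) with data for
the same year donates its values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

AGE_BIN_WIDTH = 5.0
AGE_CAP = 105.0
N_AGE_BINS = 21
AGE_COUNT_COLUMNS = [f"c_{5 * i}_{5 * (i + 1)}" for i in range(N_AGE_BINS)]

PANEL_COLUMNS = ["subsector_id", "year", "median_income", *AGE_COUNT_COLUMNS,
                 "centroid_x_m", "centroid_y_m"]


class EmptyNeighborhoodError(ValueError):
    """A neighborhood has no residents, so its median age is undefined."""


class CovariateAttachmentError(LookupError):
    """No subsector carries covariate data for a requested year."""


def grouped_median_age(age_counts) -> float:
    """Median age from 5-year grouped counts.

    Uses the classical interpolation: with N the total count, find the
    first bin whose cumulative count reaches N/2 and return
    ``L + ((N/2 - CF) / f) * h`` where L is the bin's lower bound, CF the
    cumulative count below it, f its count, and h = 5 the bin width.
    """
    counts = np.asarray(age_counts, dtype=float)
    if counts.shape != (N_AGE_BINS,):
        raise ValueError(f"expected {N_AGE_BINS} age-group counts, got shape {counts.shape}")
    if np.any(counts < 0):
        raise ValueError("age-group counts must be non-negative")
    total = counts.sum()
    if total < 1:
        raise EmptyNeighborhoodError("all age-group counts are zero; median age undefined")
    half = total / 2.0
    cumulative = np.cumsum(counts)
    k = int(np.searchsorted(cumulative, half))
    lower = AGE_BIN_WIDTH * k
    below = cumulative[k - 1] if k > 0 else 0.0
    return float(lower + (half - below) / counts[k] * AGE_BIN_WIDTH)


def load_panel(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(PANEL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"neighborhood panel missing columns: {sorted(missing)}")
    return frame


def panel_median_ages(panel: pd.DataFrame) -> pd.Series:
    """Grouped-data median age for every (subsector, year) panel row."""
    counts = panel[AGE_COUNT_COLUMNS].to_numpy(dtype=float)
    return pd.Series(
        [grouped_median_age(row) for row in counts], index=panel.index, name="nbh_median_age"
    )


def attach_covariates(records: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Attach (median income, neighborhood median age) to each record.

    Covariates come from the record's (subsector_id, death year) panel
    cell; a missing cell falls back to the nearest subsector with data for
    that year. A ``covariate_fallback`` column records whether the fallback
    fired. Raises :class:`CovariateAttachmentError` when no subsector has
    data for a record's death year.
    """
    panel = panel.copy()
    panel["nbh_median_age"] = panel_median_ages(panel)
    cell = {
        (str(s), int(y)): (inc, age)
        for s, y, inc, age in zip(
            panel["subsector_id"], panel["year"], panel["median_income"], panel["nbh_median_age"]
        )
    }
    # Subsector centroids (constant across years; first occurrence wins).
    centroids = (
        panel.drop_duplicates("subsector_id")
        .set_index(panel.drop_duplicates("subsector_id")["subsector_id"].astype(str))[
            ["centroid_x_m", "centroid_y_m"]
        ]
    )
    by_year: dict[int, pd.DataFrame] = {
        int(y): g.assign(subsector_id=g["subsector_id"].astype(str))
        for y, g in panel.groupby("year")
    }

    out = records.copy()
    death_years = pd.to_datetime(out["death_date"]).dt.year.to_numpy()
    incomes = np.empty(len(out))
    ages = np.empty(len(out))
    fallback = np.zeros(len(out), dtype=bool)

    for idx, (subsector, year) in enumerate(zip(out["subsector_id"].astype(str), death_years)):
        key = (subsector, int(year))
        if key in cell:
            incomes[idx], ages[idx] = cell[key]
            continue
        donors = by_year.get(int(year))
        if donors is None or len(donors) == 0:
            raise CovariateAttachmentError(f"no subsector has covariate data for year {year}")
        if subsector in centroids.index:
            px, py = centroids.loc[subsector]
        else:  # unknown subsector: fall back from the record's own location
            px, py = out.iloc[idx][["x_m", "y_m"]]
        d = np.hypot(
            donors["centroid_x_m"].to_numpy(dtype=float) - float(px),
            donors["centroid_y_m"].to_numpy(dtype=float) - float(py),
        )
        candidates = donors[d == d.min()]
        donor = candidates.sort_values("subsector_id").iloc[0]
        incomes[idx] = donor["median_income"]
        ages[idx] = donor["nbh_median_age"]
        fallback[idx] = True

    out["income"] = incomes
    out["nbh_median_age"] = ages
    out["covariate_fallback"] = fallback
    return out
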