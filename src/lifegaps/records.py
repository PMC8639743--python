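"""Death-record ingestion and the exclusion cascade with an auditable ledger.

Records arrive as a CSV with one row per deceased individual. Gender may be
provided directly as a column or inferred from a user-supplied given-name
lookup table; records whose gender cannot be resolved are removed by the
filter cascade (never guessed). Each filtering step logs how many rows it
removed and how many remain, so the accounting can be audited and compared
across data sources.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, shape
from shapely.geometry.base import BaseGeometry

MANDATORY_COLUMNS = ("id", "birth_date", "death_date", "nationality", "x_m", "y_m")


class DataFormatError(ValueError):
    """The input table does not conform to the expected record schema."""


@dataclass
class FilterLedger:
    """Ordered accounting of the exclusion cascade.

    Each step stores ``(step_name, n_removed, n_remaining)`` and the ledger
    enforces the telescoping identity: remaining after step k equals
    remaining after step k-1 minus removed at step k.
    """

    n_initial: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add_step(self, name: str, n_removed: int) -> None:
        prev = self.steps[-1][2] if self.steps else self.n_initial
        n_removed = int(n_removed)
        if n_removed < 0 or n_removed > prev:
            raise ValueError(f"step {name!r}: invalid removal count {n_removed}")
        self.steps.append((name, n_removed, prev - n_removed))

    @classmethod
    def from_counts(cls, n_initial: int, removals: list[tuple[str, int]]) -> "FilterLedger":
        """Replay a cascade from printed step counts."""
        ledger = cls(n_initial=int(n_initial))
        for name, n_removed in removals:
            ledger.add_step(name, n_removed)
        return ledger

    @property
    def n_remaining(self) -> int:
        return self.steps[-1][2] if self.steps else self.n_initial

    @property
    def retention_pct(self) -> float:
        """Percent of the initial records retained at the end of the cascade."""
        if self.n_initial == 0:
            return 100.0
        return 100.0 * self.n_remaining / self.n_initial

    def validate(self) -> None:
        prev = self.n_initial
        for name, removed, remaining in self.steps:
            if removed < 0 or remaining < 0 or remaining != prev - removed:
                raise ValueError(f"ledger telescoping identity violated at step {name!r}")
            prev = remaining

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step_name", "n_removed", "n_remaining"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "n_initial": self.n_initial,
                "steps": [
                    {"step_name": s, "n_removed": r, "n_remaining": k} for s, r, k in self.steps
                ],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def load_name_gender_lookup(path: str | Path) -> dict[str, str]:
    """Read a two-column (name, gender) CSV into a lookup mapping."""
    frame = pd.read_csv(path)
    missing = {"name", "gender"} - set(frame.columns)
    if missing:
        raise DataFormatError(f"name-gender lookup missing columns: {sorted(missing)}")
    return {str(n).strip().lower(): str(g) for n, g in zip(frame["name"], frame["gender"])}


def _parse_dates(series: pd.Series, column: str) -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce", format="ISO8601")
    originally_missing = series.isna() | (series.astype(str).str.strip() == "")
    bad = parsed.isna() & ~originally_missing
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataFormatError(
            f"unparseable {column} at row {row}: {series.iloc[row]!r} (expected ISO-8601)"
        )
    return parsed


def load_records(
    path: str | Path, name_gender_lookup: dict[str, str] | None = None
) -> pd.DataFrame:
    """Load a death-record CSV into the canonical record table.

    If the file carries an explicit ``gender`` column it is used as-is and
    the lookup is ignored. Otherwise gender is filled from
    ``name_gender_lookup`` keyed on the ``given_name`` column (case
    insensitive); names absent from the lookup leave gender missing, to be
    removed later by the filter cascade.
    """
    frame = pd.read_csv(path, dtype={"id": str})
    missing = set(MANDATORY_COLUMNS) - set(frame.columns)
    if missing:
        raise DataFormatError(f"missing mandatory columns: {sorted(missing)}")

    frame["birth_date"] = _parse_dates(frame["birth_date"], "birth_date")
    frame["death_date"] = _parse_dates(frame["death_date"], "death_date")

    if "gender" not in frame.columns:
        if name_gender_lookup is not None and "given_name" in frame.columns:
            names = frame["given_name"].astype(str).str.strip().str.lower()
            frame["gender"] = names.map(name_gender_lookup)
        else:
            frame["gender"] = pd.Series([pd.NA] * len(frame), dtype=object)
    if "subsector_id" not in frame.columns:
        frame["subsector_id"] = pd.NA

    both = frame["birth_date"].notna() & frame["death_date"].notna()
    reversed_dates = both & (frame["death_date"] < frame["birth_date"])
    if reversed_dates.any():
        row = int(np.flatnonzero(reversed_dates.to_numpy())[0])
        raise DataFormatError(f"death_date precedes birth_date at row {row}")
    return frame


def _as_geometry(region_boundary) -> BaseGeometry | None:
    if region_boundary is None:
        return None
    if isinstance(region_boundary, BaseGeometry):
        return region_boundary
    if isinstance(region_boundary, dict):  # GeoJSON geometry or Feature
        geom = region_boundary.get("geometry", region_boundary)
        return shape(geom)
    if isinstance(region_boundary, (tuple, list)) and len(region_boundary) == 4:
        return box(*region_boundary)
    raise TypeError("region_boundary must be a shapely geometry, GeoJSON dict, or bbox tuple")


def read_region_geojson(path: str | Path) -> BaseGeometry:
    """Read a region boundary from a GeoJSON file (Polygon feature or geometry)."""
    data = json.loads(Path(path).read_text())
    if data.get("type") == "FeatureCollection":
        data = data["features"][0]
    return _as_geometry(data)


def filter_records(
    records: pd.DataFrame,
    year_range: tuple[int, int],
    region_boundary=None,
) -> tuple[pd.DataFrame, FilterLedger]:
    """Apply the exclusion cascade and return the kept records with a ledger.

    Steps, in order:

    1. keep deaths whose death year lies in ``year_range`` (inclusive);
    2. remove duplicated entries and records missing birth date, death
       date, or nationality (one combined step);
    3. remove records located outside ``region_boundary``
       (boundary-inclusive containment);
    4. remove records without coordinates (could not be georeferenced);
    5. remove records with unresolved gender.

    An empty input yields an empty output with a zeroed ledger.
    """
    ledger = FilterLedger(n_initial=len(records))
    kept = records.copy()

    death_year = pd.to_datetime(kept["death_date"], errors="coerce").dt.year
    in_range = death_year.isna() | ((death_year >= year_range[0]) & (death_year <= year_range[1]))
    ledger.add_step("death_year_in_range", int((~in_range).sum()))
    kept = kept[in_range]

    missing_fields = (
        kept["birth_date"].isna() | kept["death_date"].isna() | kept["nationality"].isna()
    )
    # Duplicates: identical (gender, birth_date, death_date, location); keep first.
    dup_key = kept[["gender", "birth_date", "death_date", "x_m", "y_m"]]
    duplicated = dup_key.duplicated(keep="first") & ~missing_fields
    drop = missing_fields | duplicated
    ledger.add_step("duplicate_or_missing_fields", int(drop.sum()))
    kept = kept[~drop]

    geom = _as_geometry(region_boundary)
    if geom is not None:
        has_xy = kept["x_m"].notna() & kept["y_m"].notna()
        inside = np.zeros(len(kept), dtype=bool)
        if has_xy.any():
            pts = shapely.points(
                kept.loc[has_xy, "x_m"].to_numpy(dtype=float),
                kept.loc[has_xy, "y_m"].to_numpy(dtype=float),
            )
            inside[has_xy.to_numpy()] = shapely.covers(geom, pts)
        outside = has_xy.to_numpy() & ~inside
    else:
        outside = np.zeros(len(kept), dtype=bool)
    ledger.add_step("outside_region", int(outside.sum()))
    kept = kept[~outside]

    no_coords = kept["x_m"].isna() | kept["y_m"].isna()
    ledger.add_step("not_georeferenced", int(no_coords.sum()))
    kept = kept[~no_coords]

    no_gender = kept["gender"].isna()
    ledger.add_step("missing_gender", int(no_gender.sum()))
    kept = kept[~no_gender]

    ledger.validate()
    if len(kept) == 0 and len(records) > 0:
        warnings.warn("all records removed by the filter cascade", stacklevel=2)
    return kept.reset_index(drop=True), ledger
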