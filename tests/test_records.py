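import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifegaps.records import (
    DataFormatError,
    FilterLedger,
    filter_records,
    load_records,
)
from lifegaps.synthetic import SyntheticConfig, generate_population, write_outputs

YEARS = (2009, 2016)


def _write(tmp_path, frame):
    path = tmp_path / "records.csv"
    frame.to_csv(path, index=False)
    return path


def _base_frame(n=4):
    return pd.DataFrame(
        {
            "id": [f"r{i}" for i in range(n)],
            "gender": ["F", "M", "F", "M"][:n],
            "nationality": ["swiss"] * n,
            "birth_date": ["1930-01-01"] * n,
            "death_date": ["2010-06-01"] * n,
            "x_m": np.linspace(100, 400, n),
            "y_m": np.linspace(100, 400, n),
            "subsector_id": ["S0000"] * n,
        }
    )


class TestLoadRecords:
    def test_explicit_gender_column_ignores_lookup(self, tmp_path):
        frame = _base_frame()
        frame["given_name"] = ["alice", "bob", "carol", "dan"]
        records = load_records(_write(tmp_path, frame), {"alice": "M"})
        assert records["gender"].tolist() == ["F", "M", "F", "M"]

    def test_gender_filled_from_lookup(self, tmp_path):
        frame = _base_frame().drop(columns=["gender"])
        frame["given_name"] = ["Alice", "bob", "zz-unknown", "dan"]
        records = load_records(_write(tmp_path, frame), {"alice": "F", "bob": "M", "dan": "M"})
        assert records["gender"].tolist()[:2] == ["F", "M"]
        assert pd.isna(records["gender"].iloc[2])

    def test_no_gender_and_no_lookup_leaves_missing(self, tmp_path):
        frame = _base_frame().drop(columns=["gender"])
        records = load_records(_write(tmp_path, frame))
        assert records["gender"].isna().all()

    def test_missing_mandatory_column_names_it(self, tmp_path):
        frame = _base_frame().drop(columns=["nationality"])
        with pytest.raises(DataFormatError, match="nationality"):
            load_records(_write(tmp_path, frame))

    def test_unparseable_date_reports_row(self, tmp_path):
        frame = _base_frame()
        frame.loc[2, "birth_date"] = "not-a-date"
        with pytest.raises(DataFormatError, match="row 2"):
            load_records(_write(tmp_path, frame))


class TestFilterCascade:
    def test_printed_count_replay(self):
        """The published exclusion accounting telescopes to 22,751 (81.6%)."""
        ledger = FilterLedger.from_counts(
            27_889,
            [
                ("duplicate_or_missing_fields", 408),
                ("outside_region", 2_094),
                ("not_georeferenced", 1_025),
                ("missing_gender", 1_611),
            ],
        )
        ledger.validate()
        assert ledger.n_remaining == 22_751
        assert round(ledger.retention_pct, 1) == 81.6

    def test_no_exclusions_gives_zeroed_ledger(self, tmp_path):
        records = load_records(_write(tmp_path, _base_frame()))
        kept, ledger = filter_records(records, YEARS, (0, 0, 1000, 1000))
        assert len(kept) == len(records)
        assert all(removed == 0 for _, removed, _ in ledger.steps)

    def test_duplicate_removed_once(self, tmp_path):
        frame = _base_frame()
        frame = pd.concat([frame, frame.iloc[[0]].assign(id="dup")], ignore_index=True)
        records = load_records(_write(tmp_path, frame))
        kept, ledger = filter_records(records, YEARS, (0, 0, 1000, 1000))
        steps = dict((s, r) for s, r, _ in ledger.steps)
        assert steps["duplicate_or_missing_fields"] == 1
        assert len(kept) == 4

    def test_each_step_fires_in_order(self, tmp_path):
        frame = _base_frame(4)
        extra = pd.DataFrame(
            {
                "id": ["y", "n", "o", "g", "u"],
                "gender": ["F", "F", "F", "F", pd.NA],
                "nationality": ["swiss", pd.NA, "swiss", "swiss", "swiss"],
                "birth_date": ["1930-01-01"] * 5,
                "death_date": ["2000-06-01", "2010-06-01", "2010-06-01", "2010-06-01", "2010-06-01"],
                "x_m": [200.0, 200.0, 5000.0, np.nan, 200.0],
                "y_m": [200.0, 200.0, 5000.0, np.nan, 200.0],
                "subsector_id": ["S0000"] * 5,
            }
        )
        records = load_records(_write(tmp_path, pd.concat([frame, extra], ignore_index=True)))
        kept, ledger = filter_records(records, YEARS, (0, 0, 1000, 1000))
        assert [(s, r) for s, r, _ in ledger.steps] == [
            ("death_year_in_range", 1),
            ("duplicate_or_missing_fields", 1),
            ("outside_region", 1),
            ("not_georeferenced", 1),
            ("missing_gender", 1),
        ]
        assert len(kept) == 4

    def test_empty_input_is_not_an_error(self):
        kept, ledger = filter_records(_base_frame(0), YEARS, None)
        assert len(kept) == 0
        assert ledger.n_initial == 0
        ledger.validate()

    def test_boundary_inclusive_containment(self, tmp_path):
        frame = _base_frame(2)
        frame.loc[0, ["x_m", "y_m"]] = [1000.0, 1000.0]  # exactly on the boundary
        records = load_records(_write(tmp_path, frame))
        kept, _ = filter_records(records, YEARS, (0, 0, 1000, 1000))
        assert "r0" in set(kept["id"])

    def test_filtering_is_idempotent(self, small_population, tmp_path):
        config, records, truth, life_table, panel = small_population
        paths = write_outputs(records, truth, life_table, panel, tmp_path)
        loaded = load_records(paths["records"])
        # corrupt some rows so the first pass removes something
        loaded.loc[:20, "nationality"] = pd.NA
        loaded.loc[30:40, "gender"] = pd.NA
        kept, first = filter_records(loaded, YEARS, config.region_extent)
        assert first.n_remaining < first.n_initial
        again, second = filter_records(kept, YEARS, config.region_extent)
        assert all(removed == 0 for _, removed, _ in second.steps)
        assert len(again) == len(kept)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.integers(0, 500), min_size=0, max_size=6), st.integers(3001, 5000))
def test_ledger_telescoping_property(removals, n_initial):
    ledger = FilterLedger.from_counts(n_initial, [(f"s{i}", r) for i, r in enumerate(removals)])
    ledger.validate()
    assert ledger.n_remaining == n_initial - sum(removals)
    frame = ledger.to_frame()
    if len(frame):
        assert (frame["n_remaining"].diff().dropna() == -frame["n_removed"].iloc[1:]).all()


def test_ledger_rejects_overdraw():
    with pytest.raises(ValueError, match="invalid removal"):
        FilterLedger.from_counts(10, [("too_many", 11)])
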