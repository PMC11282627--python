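"""Dialect recoding, eligibility window, single-PSU stratum removal."""

import pandas as pd
import pytest

from delivcare import (
    MappingConfig,
    drop_single_psu_strata,
    filter_eligible,
    read_records,
    recode,
)
from delivcare.harmonize import RAW_REQUIRED_COLUMNS, SchemaError


@pytest.fixture()
def mapping():
    return MappingConfig(
        place_maps={"SVY1": {"11": "home", "21": "lower", "31": "hospital",
                             "36": "private_clinic"}},
        attendant_maps={"SVY1": {"1": "skilled", "2": "unskilled"}},
    )


def raw_frame(rows):
    """Raw dialect rows as (place_code, attendant_code, stay_value, stay_unit,
    pnc_value, pnc_unit[, months])."""
    recs = []
    for i, r in enumerate(rows):
        recs.append({
            "survey_id": "SVY1", "country_id": "C00",
            "stratum": f"S{i % 2}", "psu": f"P{i % 4}", "weight": "1.0",
            "wealth_quintile": str((i % 5) + 1),
            "months_since_birth": str(r[6]) if len(r) > 6 else "6",
            "place_code": r[0], "attendant_code": r[1],
            "stay_value": r[2], "stay_unit": r[3],
            "pnc_value": r[4], "pnc_unit": r[5],
        })
    return pd.DataFrame(recs, dtype=str)


class TestReadRecords:
    def test_well_formed_rows_are_all_read(self, tmp_path, mapping):
        path = tmp_path / "raw.csv"
        raw_frame([("11", "1", "", "", "1", "days")] * 3).to_csv(path, index=False)
        result = read_records(path, mapping)
        assert (result.n_read, result.n_malformed, len(result.records)) == (3, 0, 3)

    def test_missing_weight_column_is_a_schema_error(self, tmp_path, mapping):
        path = tmp_path / "raw.csv"
        raw_frame([("11", "1", "", "", "", "")]).drop(columns="weight").to_csv(
            path, index=False)
        with pytest.raises(SchemaError, match="weight"):
            read_records(path, mapping)

    def test_empty_file_is_an_explicit_error(self, tmp_path, mapping):
        path = tmp_path / "raw.csv"
        path.write_text(",".join(RAW_REQUIRED_COLUMNS) + "\n")
        with pytest.raises(ValueError, match="no records"):
            read_records(path, mapping)

    def test_malformed_rows_counted_and_dropped(self, tmp_path, mapping):
        df = raw_frame([("11", "1", "", "", "", "")] * 3)
        df.loc[1, "weight"] = "-2"
        df.loc[2, "psu"] = ""
        path = tmp_path / "raw.csv"
        df.to_csv(path, index=False)
        result = read_records(path, mapping)
        assert (result.n_read, result.n_malformed, len(result.records)) == (3, 2, 1)


class TestRecode:
    def test_record_counts_are_conserved(self, mapping):
        raw = raw_frame([("11", "1", "", "", "", ""), ("99", "9", "x", "y", "", "")])
        assert len(recode(raw, mapping)) == 2

    def test_unknown_place_code_becomes_missing(self, mapping):
        out = recode(raw_frame([("99", "1", "", "", "", "")]), mapping)
        assert out["place"].iloc[0] == "missing"

    def test_private_clinic_counts_as_hospital(self, mapping):
        out = recode(raw_frame([("36", "1", "", "", "", "")]), mapping)
        assert out["place"].iloc[0] == "hospital"

    @pytest.mark.parametrize(
        "stay_value,stay_unit,expected",
        [
            ("1", "day", "yes"),     # 1 day = 24 h, inclusive boundary
            ("24", "hours", "yes"),
            ("23", "hours", "no"),
            ("2", "days", "yes"),
            ("", "", "missing"),
        ],
    )
    def test_stay_duration_thresholded_at_24h(self, mapping, stay_value, stay_unit, expected):
        out = recode(raw_frame([("31", "1", stay_value, stay_unit, "", "")]), mapping)
        assert out["stay24"].iloc[0] == expected

    @pytest.mark.parametrize(
        "pnc_value,pnc_unit,expected",
        [
            ("49", "hours", "no"),   # strictly past the cutoff
            ("48", "hours", "yes"),  # inclusive boundary
            ("2", "days", "yes"),
            ("none", "", "no"),      # no check at all
            ("", "", "missing"),
        ],
    )
    def test_pnc_timing_thresholded_at_48h(self, mapping, pnc_value, pnc_unit, expected):
        out = recode(raw_frame([("31", "1", "", "", pnc_value, pnc_unit)]), mapping)
        assert out["pnc48"].iloc[0] == expected

    def test_home_birth_with_facility_stay_is_recoded_no(self, mapping):
        out = recode(raw_frame([("11", "1", "30", "hours", "", "")]), mapping)
        assert out["stay24"].iloc[0] == "no"

    def test_already_harmonized_codes_pass_through_unchanged(self):
        identity = MappingConfig(
            place_maps={"*": {c: c for c in ("home", "lower", "hospital")}},
            attendant_maps={"*": {"skilled": "skilled", "unskilled": "unskilled"}},
        )
        raw = raw_frame([("home", "unskilled", "", "", "", ""),
                         ("hospital", "skilled", "25", "hours", "1", "days")])
        raw["survey_id"] = "ANY"
        out = recode(raw, identity)
        assert out["place"].tolist() == ["home", "hospital"]
        assert out["sba"].tolist() == ["no", "yes"]
        assert out["stay24"].tolist() == ["missing", "yes"]


class TestFilterEligible:
    def test_two_year_window_is_strict(self, mapping):
        out = recode(raw_frame([
            ("11", "1", "", "", "", "", 0),
            ("11", "1", "", "", "", "", 23),
            ("11", "1", "", "", "", "", 24),
            ("11", "1", "", "", "", "", 30),
        ]), mapping)
        result = filter_eligible(out)
        assert (result.n_kept, result.n_dropped) == (2, 2)
        assert result.records["months_since_birth"].tolist() == [0, 23]

    def test_negative_months_dropped(self, mapping):
        out = recode(raw_frame([("11", "1", "", "", "", "", -1)]), mapping)
        assert filter_eligible(out).n_kept == 0

    def test_idempotent(self, mapping):
        out = recode(raw_frame([("11", "1", "", "", "", "", m) for m in (1, 10, 30)]),
                     mapping)
        once = filter_eligible(out).records
        twice = filter_eligible(once).records
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_input_gives_empty_output(self, mapping):
        out = recode(raw_frame([("11", "1", "", "", "", "")]), mapping).iloc[:0]
        result = filter_eligible(out)
        assert (result.n_kept, result.n_dropped, len(result.records)) == (0, 0, 0)


class TestDropSinglePsuStrata:
    def frame(self, cells):
        return pd.DataFrame([
            {"country_id": c, "stratum": s, "psu": p, "weight": 1.0,
             "wealth_quintile": 1, "place": "home", "sba": "no",
             "stay24": "no", "pnc48": "no"}
            for c, s, p in cells
        ])

    def test_singleton_stratum_removed(self):
        df = self.frame([("C0", "A", "1"), ("C0", "A", "2"), ("C0", "B", "1")])
        result = drop_single_psu_strata(df)
        assert result.dropped_strata == [("C0", "B")]
        assert set(result.records["stratum"]) == {"A"}

    def test_all_multi_psu_is_identity(self):
        df = self.frame([("C0", "A", "1"), ("C0", "A", "2"),
                         ("C0", "B", "1"), ("C0", "B", "2")])
        result = drop_single_psu_strata(df)
        assert result.dropped_strata == []
        pd.testing.assert_frame_equal(result.records, df)

    def test_all_single_psu_empties_the_table(self):
        df = self.frame([("C0", "A", "1"), ("C0", "B", "1")])
        result = drop_single_psu_strata(df)
        assert result.records.empty
        assert len(result.dropped_strata) == 2

    def test_same_stratum_label_counted_per_country(self):
        df = self.frame([("C0", "A", "1"), ("C0", "A", "2"), ("C1", "A", "1")])
        result = drop_single_psu_strata(df)
        assert result.dropped_strata == [("C1", "A")]
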