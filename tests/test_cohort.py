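"""Loading, validation, censoring, derivation and tabulation of cohorts."""

import math

import numpy as np
import pandas as pd
import pytest

import pafcc
from pafcc.cohort import MISSING, NO, YES

from _util import dataset_from_table


class TestLoadCohort:
    def test_round_trips_toy_records(self, toy_csv, toy_records):
        records = pafcc.load_cohort(toy_csv)
        assert records == toy_records

    def test_blank_cell_becomes_missing(self, tmp_path, toy_records):
        rec = toy_records[0]
        import dataclasses
        rec2 = dataclasses.replace(rec, repeated_blows_head=MISSING,
                                   spousal_pair_id=None)
        path = tmp_path / "c.csv"
        pafcc.write_subject_csv([rec2], path)
        assert '""' not in path.read_text()  # blank, not quoted sentinel
        (loaded,) = pafcc.load_cohort(path)
        assert loaded.repeated_blows_head == MISSING

    def test_onset_age_on_control_rejected(self, tmp_path, toy_csv):
        df = pd.read_csv(toy_csv)
        df.loc[df.status == "control", "onset_age_years"] = 50
        bad = tmp_path / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(pafcc.ValidationError, match="onset age"):
            pafcc.load_cohort(bad)

    def test_missing_required_column_names_it(self, tmp_path, toy_csv):
        df = pd.read_csv(toy_csv).drop(columns=["status"])
        bad = tmp_path / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(pafcc.SchemaError, match="status"):
            pafcc.load_cohort(bad)

    def test_duplicate_subject_id_rejected(self, tmp_path, toy_csv):
        df = pd.read_csv(toy_csv)
        df.loc[:, "subject_id"] = "same"
        bad = tmp_path / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(pafcc.ValidationError, match="duplicate"):
            pafcc.load_cohort(bad)

    def test_spousal_pair_must_link_case_and_control(self, tmp_path, toy_csv):
        df = pd.read_csv(toy_csv)
        df.loc[:, "spousal_pair_id"] = "p1"  # three members, two cases
        bad = tmp_path / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(pafcc.ValidationError, match="spousal"):
            pafcc.load_cohort(bad)

    def test_unparseable_enum_coerced_with_warning(self, tmp_path, toy_csv, caplog):
        df = pd.read_csv(toy_csv)
        df.loc[0, "constipation"] = "perhaps"
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with caplog.at_level("WARNING", logger="pafcc.cohort"):
            records = pafcc.load_cohort(path)
        assert records[0].constipation == MISSING
        assert "1 unparseable" in caplog.text


class TestCensoring:
    def _case(self, mtbi_year, onset_year=2010, flag=YES):
        return pafcc.SubjectRecord(
            subject_id="x", status="case", sex="male", age_years=70,
            onset_year=onset_year, mtbi_event=flag, mtbi_event_year=mtbi_year)

    def test_event_at_or_after_onset_recoded_to_no(self):
        rec = pafcc.apply_exposure_censoring(self._case(2012))
        assert rec.mtbi_event == NO
        rec = pafcc.apply_exposure_censoring(self._case(2010))
        assert rec.mtbi_event == NO  # same year counts as censored

    def test_event_before_onset_untouched(self):
        rec = pafcc.apply_exposure_censoring(self._case(1995))
        assert rec.mtbi_event == YES

    def test_controls_never_censored(self):
        rec = pafcc.SubjectRecord(subject_id="x", status="control", sex="male",
                                  mtbi_event=YES, mtbi_event_year=2012)
        assert pafcc.apply_exposure_censoring(rec) == rec

    def test_censoring_is_idempotent_and_never_creates_missing(self):
        once = pafcc.apply_exposure_censoring(self._case(2012))
        assert pafcc.apply_exposure_censoring(once) == once
        assert once.mtbi_event == NO  # recoded to "no event", not missing

    def test_pesticide_censoring_drops_duration(self):
        rec = pafcc.SubjectRecord(
            subject_id="x", status="case", sex="male", onset_year=2000,
            pesticide_exposure=YES, pesticide_start_year=2005,
            pesticide_duration_years=3.0)
        out = pafcc.apply_exposure_censoring(rec)
        assert out.pesticide_exposure == NO
        assert out.pesticide_duration_years is None

    def test_year_without_flag_rejected(self):
        rec = pafcc.SubjectRecord(subject_id="x", status="case", sex="male",
                                  onset_year=2010, mtbi_event=MISSING,
                                  mtbi_event_year=1999)
        with pytest.raises(pafcc.ValidationError, match="flag missing"):
            pafcc.apply_exposure_censoring(rec)

    def test_onset_year_reconstructed_from_ages(self):
        # survey 2019, age 70 -> birth 1949; onset age 60 -> onset 2009
        rec = pafcc.SubjectRecord(
            subject_id="x", status="case", sex="male", age_years=70,
            onset_age_years=60, survey_year=2019, mtbi_event=YES,
            mtbi_event_year=2009)
        assert rec.resolved_onset_year() == 2009
        assert pafcc.apply_exposure_censoring(rec).mtbi_event == NO


class TestMtbi10yr:
    @pytest.mark.parametrize("event_year, expected", [
        (1995, 1.0),   # clearly more than 10 years before 2010 onset
        (2005, 0.0),   # within the 10-year window: treated as no event
        (2000, 0.0),   # exactly 10 years: still within the window
        (1999, 1.0),
    ])
    def test_ten_year_window(self, event_year, expected):
        rec = pafcc.SubjectRecord(
            subject_id="x", status="case", sex="male", onset_year=2010,
            mtbi_event=YES, mtbi_event_year=event_year)
        assert pafcc.derive_mtbi_10yr(rec) == expected

    def test_no_event_is_zero_and_missing_propagates(self):
        rec = pafcc.SubjectRecord(subject_id="x", status="case", sex="male",
                                  mtbi_event=NO)
        assert pafcc.derive_mtbi_10yr(rec) == 0.0
        rec = pafcc.SubjectRecord(subject_id="x", status="case", sex="male")
        assert math.isnan(pafcc.derive_mtbi_10yr(rec))

    def test_control_keeps_raw_indicator(self):
        rec = pafcc.SubjectRecord(subject_id="x", status="control", sex="male",
                                  mtbi_event=YES, mtbi_event_year=2005)
        assert pafcc.derive_mtbi_10yr(rec) == 1.0


class TestCompleteCase:
    def test_identity_without_missingness(self, fixed_cohort):
        sub = pafcc.complete_case_subset(fixed_cohort, ["e", "age"])
        assert sub.n == fixed_cohort.n

    def test_counts_rows_with_missing(self):
        df = pd.DataFrame({"status": [1] * 5 + [0] * 5,
                           "x": [1, np.nan, 0, np.nan, 1, 0, 0, np.nan, 1, 0]})
        ds = pafcc.CodedDataset(df)
        sub = pafcc.complete_case_subset(ds, ["x"])
        assert sub.n == 7
        assert sub.status_counts() == (3, 4)

    def test_unknown_variable_errors(self, fixed_cohort):
        with pytest.raises(KeyError, match="nope"):
            pafcc.complete_case_subset(fixed_cohort, ["nope"])

    def test_retention_matches_binomial_expectation(self):
        rate = 0.2
        spec = pafcc.CohortSpec(n_cases=2000, n_controls=2000,
                                exposures=(pafcc.ExposureSpec("e", 0.3, 2.0),),
                                missingness={"e": rate}, seed=7)
        ds = pafcc.generate_cohort(spec)
        sub = pafcc.complete_case_subset(ds, ["e"])
        n, p = 4000, 1 - rate
        assert abs(sub.n - n * p) < 4 * math.sqrt(n * p * (1 - p))

    def test_subset_nesting_property(self):
        spec = pafcc.CohortSpec(n_cases=300, n_controls=300,
                                exposures=(pafcc.ExposureSpec("a", 0.3, 2.0),
                                           pafcc.ExposureSpec("b", 0.2, 1.5)),
                                missingness={"a": 0.2, "b": 0.15}, seed=3)
        ds = pafcc.generate_cohort(spec)
        df = ds.df.copy()
        df["row"] = range(len(df))
        ds = pafcc.CodedDataset(df)
        both = set(pafcc.complete_case_subset(ds, ["a", "b"]).df["row"])
        just_a = set(pafcc.complete_case_subset(ds, ["a"]).df["row"])
        assert both <= just_a


class TestTwoByTwo:
    def test_published_male_pesticide_counts(self):
        ds = dataset_from_table(112, 263, 15, 85)
        t = pafcc.build_two_by_two(ds, "exposure")
        assert (t.a, t.b, t.c, t.d) == (112, 263, 15, 85)
        assert t.total == ds.n

    def test_empty_and_single_status_margins(self):
        empty = pafcc.CodedDataset(pd.DataFrame({"status": [], "e": []}))
        t = pafcc.build_two_by_two(empty, "e")
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0)
        all_cases = pafcc.CodedDataset(
            pd.DataFrame({"status": [1, 1, 1], "e": [1.0, 0.0, 1.0]}))
        t = pafcc.build_two_by_two(all_cases, "e")
        assert (t.c, t.d) == (0, 0)

    def test_margins_match_complete_case_counts(self):
        spec = pafcc.CohortSpec(n_cases=200, n_controls=150,
                                exposures=(pafcc.ExposureSpec("e", 0.2, 2.0),),
                                missingness={"e": 0.1}, seed=5)
        ds = pafcc.generate_cohort(spec)
        sub = pafcc.complete_case_subset(ds, ["e"])
        t = pafcc.build_two_by_two(sub, "e")
        assert (t.n_cases, t.n_controls) == sub.status_counts()

    def test_non_binary_exposure_rejected(self, fixed_cohort):
        with pytest.raises(pafcc.ValidationError, match="not binary"):
            pafcc.build_two_by_two(fixed_cohort, "age")


class TestCoding:
    def test_coded_values_and_missing_family_history(self, toy_records):
        ds = pafcc.code_cohort(toy_records)
        assert list(ds.df["status"]) == [1, 1, 0]
        # family history: positive->1, unknown->missing, negative->0
        fh = ds.df["family_history"]
        assert fh[0] == 1.0 and math.isnan(fh[1]) and fh[2] == 0.0

    def test_sex_stratification(self, toy_records):
        males = pafcc.code_cohort(toy_records, sex="male")
        assert males.n == 2 and males.stratum == "male"

    def test_duration_zero_when_unexposed(self, toy_records):
        ds = pafcc.code_cohort(toy_records)
        assert ds.df["pesticide_duration"][2] == 0.0

    def test_censoring_applied_during_coding(self):
        rec = pafcc.SubjectRecord(
            subject_id="x", status="case", sex="male", onset_year=2010,
            mtbi_event=YES, mtbi_event_year=2012)
        ds = pafcc.code_cohort([rec])
        assert ds.df["mtbi"][0] == 0.0
        ds_raw = pafcc.code_cohort([rec], censor=False)
        assert ds_raw.df["mtbi"][0] == 1.0

    def test_censoring_never_increases_exposure_count(self):
        spec = pafcc.male_study_spec(seed=11)
        recs = pafcc.generate_subject_records(spec)
        raw = pafcc.code_cohort(recs, censor=False)
        cen = pafcc.code_cohort(recs, censor=True)
        for col in ("mtbi", "pesticide"):
            assert cen.df[col].sum() <= raw.df[col].sum()

    def test_status_coding_validated(self):
        with pytest.raises(pafcc.ValidationError, match="status"):
            pafcc.CodedDataset(pd.DataFrame({"status": [2, 0]}))
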