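import numpy as np
import pandas as pd
import pytest

from phscox.phenotypes import (
    ProgressionDataset,
    ProgressionDefinition,
    age_at_event,
    check_case_thresholds,
    clean_event_dates,
    compute_dob,
    derive_progression,
)
from phscox.simulate import gen_ehr_events

DEFN = ProgressionDefinition(
    baseline_codes={"E78"},
    outcome_codes={"K451"},
    censor_date="2020-03-01",
    min_baseline_cases=10,
    min_outcome_cases=2,
)


def _records(rows):
    return pd.DataFrame(rows, columns=["person_id", "code", "date", "source"])


class TestComputeDob:
    @pytest.mark.parametrize(
        "month,year,expected",
        [(4, 1950, "1950-04-01"), (1, 2000, "2000-01-01"), (12, 1939, "1939-12-01")],
    )
    def test_first_day_of_birth_month(self, month, year, expected):
        assert compute_dob(month, year) == pd.Timestamp(expected)

    @pytest.mark.parametrize("month", [0, 13])
    def test_invalid_month_rejected(self, month):
        with pytest.raises(ValueError):
            compute_dob(month, 1950)


class TestCleanEventDates:
    DOB = pd.Series({"a": pd.Timestamp("1950-04-01")})

    def _clean_single(self, date):
        rec = _records([("a", "E78", pd.Timestamp(date), "inpatient")])
        return clean_event_dates(rec, self.DOB)

    def test_1902_becomes_dob(self):
        cleaned, rep = self._clean_single("1902-02-02")
        assert cleaned["date"].iloc[0] == pd.Timestamp("1950-04-01")
        assert rep.to_dob_1902 == 1

    def test_1903_becomes_dob_plus_six_months(self):
        cleaned, rep = self._clean_single("1903-03-03")
        assert cleaned["date"].iloc[0] == pd.Timestamp("1950-10-01")
        assert rep.to_dob_plus_6m_1903 == 1

    @pytest.mark.parametrize("date", ["2037-07-07", "1900-01-01"])
    def test_future_and_unknown_dates_removed(self, date):
        cleaned, rep = self._clean_single(date)
        assert len(cleaned) == 0
        assert rep.total_actions() == 1

    def test_month_before_birth_moved_to_dob(self):
        cleaned, rep = self._clean_single("1950-03-15")
        assert cleaned["date"].iloc[0] == pd.Timestamp("1950-04-01")
        assert rep.month_before_birth_to_dob == 1

    def test_ordinary_date_unchanged(self):
        cleaned, rep = self._clean_single("1995-06-15")
        assert cleaned["date"].iloc[0] == pd.Timestamp("1995-06-15")
        assert rep.total_actions() == 0 and rep.unchanged == 1

    def test_missing_dob_names_the_person(self):
        rec = _records([("ghost", "E78", pd.Timestamp("1990-01-01"), "inpatient")])
        with pytest.raises(KeyError, match="ghost"):
            clean_event_dates(rec, self.DOB)

    def test_idempotent_on_generated_cohort(self):
        ehr = gen_ehr_events(200, seed=11)
        once, _ = clean_event_dates(ehr.events, ehr.dob)
        twice, rep2 = clean_event_dates(once, ehr.dob)
        assert twice.equals(once)
        assert rep2.total_actions() == 0


class TestAgeAtEvent:
    def test_event_on_dob_is_one_month(self):
        assert age_at_event("1950-04-01", "1950-04-01") == pytest.approx(1 / 12)

    def test_ten_years(self):
        assert age_at_event("1950-04-01", "1960-04-01") == pytest.approx(10.0, abs=0.01)

    def test_half_year(self):
        assert age_at_event("1950-04-01", "1950-10-01") == pytest.approx(0.5, abs=0.01)

    def test_event_before_dob_rejected(self):
        with pytest.raises(ValueError):
            age_at_event("1950-04-01", "1950-03-01")


class TestDeriveProgression:
    DOB = pd.Series(
        {
            "p1": pd.Timestamp("1950-01-01"),
            "p2": pd.Timestamp("1950-01-01"),
            "p3": pd.Timestamp("1950-01-01"),
            "p4": pd.Timestamp("1950-01-01"),
        }
    )

    def _derive(self, rows, deaths=None):
        deaths = pd.Series(deaths or {}, dtype="datetime64[ns]")
        return derive_progression(_records(rows), DEFN, deaths, self.DOB)

    def test_event_after_baseline_is_a_case(self):
        ds, rep = self._derive(
            [
                ("p1", "E78", pd.Timestamp("2000-01-01"), "inpatient"),
                ("p1", "K451", pd.Timestamp("2005-07-02"), "procedure"),
            ]
        )
        assert ds.status[0] == 1
        assert ds.y[0] == pytest.approx(5.5, abs=0.01)

    def test_outcome_before_baseline_excluded(self):
        ds, rep = self._derive(
            [
                ("p1", "E78", pd.Timestamp("2000-01-01"), "inpatient"),
                ("p1", "K451", pd.Timestamp("1999-01-01"), "procedure"),
                ("p2", "E78", pd.Timestamp("2000-01-01"), "inpatient"),
                ("p2", "K451", pd.Timestamp("2001-01-01"), "procedure"),
            ]
        )
        assert rep.excluded_by_ordering == 1
        assert list(ds.person_ids) == ["p2"]

    def test_death_before_censor_date_censors(self):
        ds, _ = self._derive(
            [("p1", "E78", pd.Timestamp("2000-01-01"), "inpatient")],
            deaths={"p1": pd.Timestamp("2010-01-01")},
        )
        assert ds.status[0] == 0
        assert ds.y[0] == pytest.approx(10.0, abs=0.01)

    def test_no_outcome_censors_at_censor_date(self):
        ds, _ = self._derive([("p1", "E78", pd.Timestamp("2000-01-01"), "inpatient")])
        expected = (pd.Timestamp("2020-03-01") - pd.Timestamp("2000-01-01")).days / 365.25
        assert ds.status[0] == 0
        assert ds.y[0] == pytest.approx(expected, abs=1e-9)

    def test_outcome_after_censor_date_treated_as_absent(self):
        ds, _ = self._derive(
            [
                ("p1", "E78", pd.Timestamp("2000-01-01"), "inpatient"),
                ("p1", "K451", pd.Timestamp("2021-01-01"), "procedure"),
            ]
        )
        assert ds.status[0] == 0

    def test_same_day_outcome_excluded_strictly(self):
        ds, rep = self._derive(
            [
                ("p1", "E78", pd.Timestamp("2000-01-01"), "inpatient"),
                ("p1", "K451", pd.Timestamp("2000-01-01"), "procedure"),
                ("p2", "E78", pd.Timestamp("2000-01-01"), "inpatient"),
                ("p2", "K451", pd.Timestamp("2001-01-01"), "procedure"),
            ]
        )
        assert rep.excluded_by_ordering == 1

    def test_three_char_prefix_matches_diagnosis_codes(self):
        ds, _ = self._derive(
            [
                ("p1", "E780", pd.Timestamp("2000-01-01"), "inpatient"),  # prefix E78
                ("p1", "K451", pd.Timestamp("2001-01-01"), "procedure"),
            ]
        )
        assert ds.status[0] == 1

    def test_partition_is_exhaustive_and_disjoint(self):
        ehr = gen_ehr_events(300, seed=12)
        cleaned, _ = clean_event_dates(ehr.events, ehr.dob)
        ds, rep = derive_progression(cleaned, DEFN, ehr.deaths, ehr.dob)
        assert rep.included + rep.excluded_by_ordering + rep.no_baseline == 300
        assert rep.included == len(ds)
        assert (ds.y > 0).all()
        assert set(np.unique(ds.status)) <= {0, 1}

    def test_empty_dataset_is_an_error(self):
        with pytest.raises(ValueError):
            self._derive([("p1", "Z99", pd.Timestamp("2000-01-01"), "inpatient")])


class TestCaseThresholds:
    def _dataset(self, n, cases):
        status = np.zeros(n, dtype=int)
        status[:cases] = 1
        return ProgressionDataset(
            person_ids=np.array([f"p{i}" for i in range(n)]),
            y=np.ones(n),
            status=status,
            covariates=pd.DataFrame({"age_at_baseline": np.full(n, 50.0)}),
        )

    def test_default_thresholds_pass(self):
        defn = ProgressionDefinition({"E78"}, {"K451"}, "2020-03-01")
        check = check_case_thresholds(self._dataset(16_000, 500), defn)
        assert check.passed and check.n_baseline == 16_000 and check.n_cases == 500

    def test_exact_threshold_fails_strictly(self):
        defn = ProgressionDefinition({"E78"}, {"K451"}, "2020-03-01")
        assert not check_case_thresholds(self._dataset(16_000, 400), defn).passed

    def test_zero_events_fail(self):
        assert not check_case_thresholds(self._dataset(100, 0), DEFN).passed

    def test_disjoint_code_sets_required(self):
        with pytest.raises(ValueError):
            ProgressionDefinition({"E78"}, {"E78"}, "2020-03-01")
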