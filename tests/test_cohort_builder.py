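"""Cohort inclusion rules, index assignment, CHA2DS2-VASc, baseline meds."""

import itertools

import pandas as pd
import pytest
from conftest import make_dispensing

from oacdur import baseline_medication_profile, cha2ds2_vasc, identify_af_cohort
from oacdur.cohort_builder import (
    age_at,
    assign_index_and_end,
    build_cohort,
)
from oacdur.errors import ConfigurationError
from oacdur.exposure_episodes import ANY_DOAC
from oacdur import cohort_events


def hospital_of(rows):
    """Rows of (patient_id, admission_date, codes)."""
    return pd.DataFrame(
        [
            {
                "patient_id": pid,
                "admission_date": pd.Timestamp(adm),
                "discharge_date": pd.Timestamp(adm) + pd.Timedelta(days=2),
                "diagnosis_codes": codes,
            }
            for pid, adm, codes in rows
        ]
    )


STUDY_END = pd.Timestamp("2014-06-30")


class TestIdentifyAfCohort:
    def disp(self, pid, date, drug):
        d = make_dispensing([(0, drug, 28)], patient_id=pid)
        d["dispense_date"] = pd.Timestamp(date)
        return d

    def test_af_plus_eligible_rivaroxaban_included(self):
        hosp = hospital_of([("P1", "2012-06-01", "I48")])
        disp = self.disp("P1", "2013-05-01", "rivaroxaban")
        assert identify_af_cohort(hosp, disp, study_end=STUDY_END) == {"P1"}

    def test_doac_without_af_episode_excluded(self):
        hosp = hospital_of([("P1", "2012-06-01", "I509")])
        disp = self.disp("P1", "2013-05-01", "rivaroxaban")
        assert identify_af_cohort(hosp, disp, study_end=STUDY_END) == set()

    def test_dispensing_before_approval_excluded(self):
        # dabigatran approved September 2011
        hosp = hospital_of([("P1", "2010-06-01", "I481")])
        disp = self.disp("P1", "2011-06-01", "dabigatran")
        assert identify_af_cohort(hosp, disp, study_end=STUDY_END) == set()

    def test_af_code_any_position(self):
        hosp = hospital_of([("P1", "2012-06-01", "I509;I48.1")])
        disp = self.disp("P1", "2013-05-01", "rivaroxaban")
        assert identify_af_cohort(hosp, disp, study_end=STUDY_END) == {"P1"}

    def test_af_after_first_doac_excluded(self):
        hosp = hospital_of([("P1", "2013-06-01", "I48")])
        disp = self.disp("P1", "2013-05-01", "rivaroxaban")
        assert identify_af_cohort(hosp, disp, study_end=STUDY_END) == set()

    def test_unknown_doac_in_approval_lookup_errors(self):
        hosp = hospital_of([("P1", "2012-06-01", "I48")])
        disp = self.disp("P1", "2013-05-01", "rivaroxaban")
        with pytest.raises(ConfigurationError):
            identify_af_cohort(hosp, disp, approval_dates={"apixaban": "2013-01-01"})


class TestAssignIndexAndEnd:
    def test_earliest_doac_wins(self):
        disp = make_dispensing(
            [(100, "rivaroxaban", 28), (150, "apixaban", 56)]
        )
        row = assign_index_and_end("P1", disp, object(), STUDY_END)
        assert row["index_drug"] == "rivaroxaban"
        assert row["index_date"] == disp["dispense_date"].min()

    def test_exit_before_study_end(self):
        disp = make_dispensing([(0, "rivaroxaban", 28)])

        class Demo:
            exit_date = pd.Timestamp("2013-06-01")

        row = assign_index_and_end("P1", disp, Demo(), STUDY_END)
        assert row["end_date"] == pd.Timestamp("2013-06-01")

    def test_same_day_tie_broken_alphabetically(self):
        disp = make_dispensing([(0, "rivaroxaban", 28), (0, "dabigatran", 56)])
        row = assign_index_and_end("P1", disp, object(), STUDY_END)
        assert row["index_drug"] == "dabigatran"

    def test_tie_break_does_not_affect_any_doac_rates(self):
        """Either index-drug label gives identical any-DOAC events."""
        disp = make_dispensing([(0, "rivaroxaban", 28), (0, "dabigatran", 56), (90, "rivaroxaban", 28)])
        results = []
        for label in ("dabigatran", "rivaroxaban"):
            cohort = pd.DataFrame(
                [
                    {
                        "patient_id": "P1",
                        "index_date": disp["dispense_date"].min(),
                        "index_drug": label,
                        "end_date": disp["dispense_date"].min() + pd.Timedelta(days=300),
                        "days_in_study": 300,
                    }
                ]
            )
            ev = cohort_events(disp, cohort, ANY_DOAC)
            results.append(
                ev[["discontinued", "ceased", "pathway"]].iloc[0].tolist()
            )
        assert results[0] == results[1]


class TestCha2ds2Vasc:
    # (sex, age, codes, expected) spanning the whole 0-9 scale
    VIGNETTES = [
        ("male", 40, [], 0),
        ("male", 70, [], 1),
        ("female", 70, [], 2),
        ("female", 80, ["I10"], 4),  # sex 1 + age 2 + hypertension 1
        ("male", 80, ["I10"], 3),
        ("male", 77, ["I509", "E119", "I638"], 2 + 1 + 1 + 2),
        ("female", 70, ["I509", "E11", "I63"], 1 + 1 + 1 + 1 + 2),  # = 6
        ("female", 80, ["I509", "I10", "E119", "I702"], 7),
        ("female", 80, ["I509", "I10", "E119", "I639"], 8),
        ("female", 80, ["I50", "I10", "E11", "I63", "I70"], 9),
    ]

    @pytest.mark.parametrize("sex, age, codes, expected", VIGNETTES)
    def test_vignettes(self, sex, age, codes, expected):
        assert cha2ds2_vasc(sex, age, codes) == expected

    def test_monotone_in_comorbidities(self):
        """Adding any qualifying comorbidity never lowers the score."""
        component_codes = ["I50", "I10", "E11", "I63", "I70", "G45"]
        for sex, age in itertools.product(("male", "female"), (40, 70, 80)):
            for r in range(len(component_codes)):
                for subset in itertools.combinations(component_codes, r):
                    base = cha2ds2_vasc(sex, age, list(subset))
                    for extra in component_codes:
                        assert cha2ds2_vasc(sex, age, list(subset) + [extra]) >= base

    def test_duplicate_codes_not_double_counted(self):
        assert cha2ds2_vasc("male", 40, ["I10", "I101", "I15"]) == 1

    def test_tia_counts_as_stroke_component(self):
        assert cha2ds2_vasc("male", 40, ["G459"]) == 2

    def test_incomplete_code_map_errors(self):
        with pytest.raises(ConfigurationError):
            cha2ds2_vasc("male", 40, [], code_map={"chf": ("I50",)})


class TestBaselineMedication:
    def test_prior_vka_flag(self):
        disp = make_dispensing([(-30, "warfarin", 28), (0, "rivaroxaban", 28)])
        prof = baseline_medication_profile(disp, disp["dispense_date"].max(), "rivaroxaban")
        assert prof["prior_vka"] is True

    def test_window_boundaries_half_open(self):
        """Exactly 183 days before index is inside; the index date is not."""
        index = pd.Timestamp("2013-07-03")
        disp = make_dispensing([(0, "warfarin", 28), (183, "aspirin", 28)])
        # day 0 = 2013-01-01 = index - 183; day 183 = index date
        prof = baseline_medication_profile(disp, index, "rivaroxaban")
        assert prof["prior_vka"] is True  # the 183-days-before row counts
        assert prof["aspirin"] is False  # the index-date row does not

    def test_avoid_vs_contraindicated_per_index_drug(self):
        disp = make_dispensing([(-30, "clarithromycin", 28), (0, "dabigatran", 56)])
        index = disp["dispense_date"].max()
        dab = baseline_medication_profile(disp, index, "dabigatran")
        assert dab["avoid"] is True and dab["contraindicated"] is False
        riv = baseline_medication_profile(disp, index, "rivaroxaban")
        assert riv["avoid"] is True and riv["contraindicated"] is False

    def test_contraindicated_ketoconazole_for_dabigatran(self):
        disp = make_dispensing([(-10, "ketoconazole", 14), (0, "dabigatran", 56)])
        prof = baseline_medication_profile(disp, disp["dispense_date"].max(), "dabigatran")
        assert prof["contraindicated"] is True

    def test_distinct_drug_count(self):
        names = [f"drug{i}" for i in range(12)]
        rows = [(-(i + 1), n, 28) for i, n in enumerate(names)]
        rows += [(-5, "drug0", 28)]  # duplicate name, not double-counted
        disp = make_dispensing(rows + [(0, "rivaroxaban", 28)])
        prof = baseline_medication_profile(disp, disp["dispense_date"].max(), "rivaroxaban")
        assert prof["n_distinct_drugs_baseline"] == 12


class TestBuildCohort:
    def test_end_to_end_small_fixture(self):
        disp = pd.concat(
            [
                make_dispensing([(0, "rivaroxaban", 28), (28, "rivaroxaban", 28)], "A"),
                make_dispensing([(10, "apixaban", 56)], "B"),
                make_dispensing([(5, "rivaroxaban", 28)], "C"),  # no AF episode
            ],
            ignore_index=True,
        )
        hosp = hospital_of(
            [
                ("A", "2012-05-01", "I48"),
                ("B", "2011-01-01", "I481;I10"),
                ("C", "2012-01-01", "I509"),
            ]
        )
        demo = pd.DataFrame(
            {
                "patient_id": ["A", "B", "C"],
                "sex": ["female", "male", "male"],
                "birth_date": pd.to_datetime(["1940-01-01", "1960-06-15", "1950-01-01"]),
                "exit_date": [pd.NaT, pd.Timestamp("2013-06-01"), pd.NaT],
                "exit_reason": ["none", "death", "none"],
            }
        )
        cohort = build_cohort(disp, hosp, demo, STUDY_END)
        assert set(cohort["patient_id"]) == {"A", "B"}
        a = cohort.set_index("patient_id").loc["A"]
        assert a["index_drug"] == "rivaroxaban"
        assert a["age_at_index"] == 73  # born 1940-01-01, index 2013-01-01
        assert a["cha2ds2vasc"] == 2  # female + age 65-74
        b = cohort.set_index("patient_id").loc["B"]
        assert b["end_date"] == pd.Timestamp("2013-06-01")
        # invariants: index <= end and approval <= index
        assert (cohort["index_date"] <= cohort["end_date"]).all()

    def test_extra_exclusion_predicates(self):
        disp = make_dispensing([(0, "rivaroxaban", 28)], "A")
        hosp = hospital_of([("A", "2012-05-01", "I48")])
        demo = pd.DataFrame(
            {
                "patient_id": ["A"],
                "sex": ["male"],
                "birth_date": [pd.Timestamp("1940-01-01")],
                "exit_date": [pd.NaT],
                "exit_reason": ["none"],
            }
        )
        keep = build_cohort(disp, hosp, demo, STUDY_END)
        drop = build_cohort(
            disp, hosp, demo, STUDY_END,
            extra_exclusions=[lambda row, d, h: row["age_at_index"] > 70],
        )
        assert len(keep) == 1 and len(drop) == 0


def test_age_at_handles_birthday_boundary():
    b = pd.Timestamp("1940-06-15")
    assert age_at(b, pd.Timestamp("2000-06-14")) == 59
    assert age_at(b, pd.Timestamp("2000-06-15")) == 60
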