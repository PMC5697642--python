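"""Cohort identification and baseline characterisation.

The cohort comprises patients with atrial fibrillation confirmed in
secondary care (an AF ICD-10 code in any diagnostic position, on or before
their first eligible DOAC dispensing) who received a first DOAC between
the drug's approval for stroke prevention in AF and the study end.  The
index date is the date of the first eligible DOAC dispensing; a patient's
end date is death/deregistration or the study end, whichever is first.

Baseline characterisation uses hospital records from the five years
before the index date (CHA2DS2-VASc components, from hospital records
only) and dispensings from the six months before the index date
(prior VKA use, concomitant antiplatelet/aspirin/NSAID, interacting
drugs, polypharmacy).  Six months is realised as 183 days, five years as
1826 days, both half-open at the index date: a dispensing exactly 183
days before the index is inside the window, one on the index date is not.
"""

from __future__ import annotations

import logging
from datetime import date

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError
from .vocab import (
    AF_CODE_PREFIXES,
    APPROVAL_DATES,
    AVOID_DRUGS,
    CHA2DS2VASC_CODE_MAP,
    CHA2DS2VASC_COMPONENTS,
    CLASS_ANTIPLATELET,
    CLASS_ASPIRIN,
    CLASS_NSAID,
    CLASS_VKA,
    CONTRAINDICATED_DRUGS,
    code_matches,
    is_doac_class,
    normalise_icd10,
)

logger = logging.getLogger(__name__)

BASELINE_MEDICATION_DAYS = 183  # "6 months"
BASELINE_HOSPITAL_DAYS = 1826  # "5 years"
AF_LOOKBACK_START = pd.Timestamp(1997, 1, 1)
POLYPHARMACY_THRESHOLD = 5

REQUIRED_DISPENSING_COLS = (
    "patient_id",
    "dispense_date",
    "drug_name",
    "drug_class",
    "quantity",
)
REQUIRED_HOSPITAL_COLS = ("patient_id", "admission_date", "diagnosis_codes")
REQUIRED_DEMOGRAPHICS_COLS = ("patient_id", "sex", "birth_date")


def _check_columns(df: pd.DataFrame, required, table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing columns: {missing}")


def _codes_as_list(codes) -> list[str]:
    """Diagnosis codes may be stored as a list or a ';'-joined string."""
    if isinstance(codes, str):
        return [c for c in codes.split(";") if c]
    if codes is None or (isinstance(codes, float) and np.isnan(codes)):
        return []
    return list(codes)


def _approval_ts(approval_dates: dict) -> dict[str, pd.Timestamp]:
    out = {}
    for drug, d in approval_dates.items():
        out[drug] = pd.Timestamp(d) if isinstance(d, (date, str)) else d
    return out


# ---------------------------------------------------------------------------
# Cohort identification


def eligible_doac_dispensings(
    dispensing: pd.DataFrame,
    approval_dates: dict = APPROVAL_DATES,
    study_end: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """DOAC dispensings on/after the drug's approval date and on/before
    study end; an unknown DOAC name raises a configuration error."""
    _check_columns(dispensing, REQUIRED_DISPENSING_COLS, "dispensing")
    approvals = _approval_ts(approval_dates)
    doac = dispensing.loc[dispensing["drug_class"].map(is_doac_class)].copy()
    unknown = set(doac["drug_name"]) - set(approvals)
    if unknown:
        raise ConfigurationError(
            f"no approval date configured for DOAC(s): {sorted(unknown)}"
        )
    ok = doac["dispense_date"] >= doac["drug_name"].map(approvals)
    if study_end is not None:
        ok &= doac["dispense_date"] <= study_end
    return doac.loc[ok]


def first_af_dates(
    hospital: pd.DataFrame,
    af_code_prefixes=AF_CODE_PREFIXES,
    window_start: pd.Timestamp = AF_LOOKBACK_START,
) -> pd.Series:
    """Earliest admission date carrying an AF code, per patient (any
    diagnostic position)."""
    _check_columns(hospital, REQUIRED_HOSPITAL_COLS, "hospital")
    mask = hospital["diagnosis_codes"].map(
        lambda cs: any(code_matches(c, af_code_prefixes) for c in _codes_as_list(cs))
    )
    af = hospital.loc[mask & (hospital["admission_date"] >= window_start)]
    return af.groupby("patient_id")["admission_date"].min()


def identify_af_cohort(
    hospital: pd.DataFrame,
    dispensing: pd.DataFrame,
    approval_dates: dict = APPROVAL_DATES,
    *,
    study_end: pd.Timestamp | None = None,
    af_code_prefixes=AF_CODE_PREFIXES,
) -> set:
    """Patients with secondary-care-confirmed AF on or before their first
    eligible DOAC dispensing."""
    eligible = eligible_doac_dispensings(dispensing, approval_dates, study_end)
    if eligible.empty:
        return set()
    first_doac = eligible.groupby("patient_id")["dispense_date"].min()
    af_dates = first_af_dates(hospital, af_code_prefixes)
    both = first_doac.index.intersection(af_dates.index)
    ok = af_dates.loc[both] <= first_doac.loc[both]
    return set(ok.index[ok])


def assign_index_and_end(
    patient_id,
    dispensings: pd.DataFrame,
    demographics_row,
    study_end: pd.Timestamp,
    approval_dates: dict = APPROVAL_DATES,
) -> dict | None:
    """Index date/drug and end date for one cohort patient.

    Index = earliest eligible DOAC dispensing; same-day ties between two
    DOACs are broken alphabetically by drug name (deterministic; affects
    only the index-drug label).  End = min(exit date, study end).  Returns
    None (with a logged reason) if the index postdates the end date.
    """
    eligible = eligible_doac_dispensings(dispensings, approval_dates, study_end)
    eligible = eligible.sort_values(["dispense_date", "drug_name"], kind="stable")
    first = eligible.iloc[0]
    index_date = first["dispense_date"]
    exit_date = getattr(demographics_row, "exit_date", None)
    end_date = study_end
    if exit_date is not None and not pd.isna(exit_date):
        end_date = min(pd.Timestamp(exit_date), study_end)
    if index_date > end_date:
        logger.warning(
            "patient %s excluded: index date %s after end date %s",
            patient_id,
            index_date.date(),
            end_date.date(),
        )
        return None
    return {
        "patient_id": patient_id,
        "index_date": index_date,
        "index_drug": first["drug_name"],
        "end_date": end_date,
        "days_in_study": int((end_date - index_date).days),
    }


# ---------------------------------------------------------------------------
# Baseline characterisation


def age_at(birth_date: pd.Timestamp, when: pd.Timestamp) -> int:
    """Completed years of age at ``when``."""
    years = when.year - birth_date.year
    if (when.month, when.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def cha2ds2_vasc(
    sex: str,
    age: int,
    diagnosis_codes,
    code_map: dict[str, tuple[str, ...]] = CHA2DS2VASC_CODE_MAP,
) -> int:
    """CHA2DS2-VASc stroke-risk score (0-9) from hospital diagnosis codes.

    One point each for congestive heart failure, hypertension, diabetes,
    vascular disease, age 65-74 and female sex; two points each for age
    >= 75 and prior stroke/TIA.
    """
    missing = [c for c in CHA2DS2VASC_COMPONENTS if c not in code_map]
    if missing:
        raise ConfigurationError(f"code map missing components: {missing}")
    codes = [normalise_icd10(c) for c in diagnosis_codes]
    has = {
        comp: any(code_matches(c, prefixes) for c in codes)
        for comp, prefixes in code_map.items()
    }
    score = 0
    score += has["chf"]
    score += has["hypertension"]
    score += has["diabetes"]
    score += 2 * has["stroke_tia"]
    score += has["vascular"]
    if age >= 75:
        score += 2
    elif age >= 65:
        score += 1
    score += sex == "female"
    return score


def baseline_hospital_codes(
    episodes: pd.DataFrame, index_date: pd.Timestamp
) -> list[str]:
    """All diagnosis codes from admissions in the 5-year pre-index window
    (half-open at the index date)."""
    lo = index_date - pd.Timedelta(days=BASELINE_HOSPITAL_DAYS)
    window = episodes.loc[
        (episodes["admission_date"] >= lo) & (episodes["admission_date"] < index_date)
    ]
    out: list[str] = []
    for cs in window["diagnosis_codes"]:
        out.extend(_codes_as_list(cs))
    return out


def baseline_medication_profile(
    dispensings: pd.DataFrame,
    index_date: pd.Timestamp,
    index_drug: str,
    *,
    contraindicated: dict = CONTRAINDICATED_DRUGS,
    avoid: dict = AVOID_DRUGS,
) -> dict:
    """Concomitant-medication flags and distinct-drug count over the
    183-day window before (and excluding) the index date."""
    lo = index_date - pd.Timedelta(days=BASELINE_MEDICATION_DAYS)
    w = dispensings.loc[
        (dispensings["dispense_date"] >= lo)
        & (dispensings["dispense_date"] < index_date)
    ]
    names = set(w["drug_name"])
    classes = set(w["drug_class"])
    return {
        "prior_vka": CLASS_VKA in classes,
        "antiplatelet": CLASS_ANTIPLATELET in classes,
        "aspirin": CLASS_ASPIRIN in classes,
        "nsaid": CLASS_NSAID in classes,
        "contraindicated": bool(names & contraindicated.get(index_drug, frozenset())),
        "avoid": bool(names & avoid.get(index_drug, frozenset())),
        "n_distinct_drugs_baseline": len(names),
    }


# ---------------------------------------------------------------------------
# Orchestration


def build_cohort(
    dispensing: pd.DataFrame,
    hospital: pd.DataFrame,
    demographics: pd.DataFrame,
    study_end: pd.Timestamp,
    *,
    approval_dates: dict = APPROVAL_DATES,
    af_code_prefixes=AF_CODE_PREFIXES,
    code_map: dict = CHA2DS2VASC_CODE_MAP,
    extra_exclusions=(),
) -> pd.DataFrame:
    """One row per included patient, with index/end dates and baseline
    characteristics.

    ``extra_exclusions`` are optional predicates ``f(cohort_row: dict,
    dispensings, episodes) -> bool`` applied after the built-in inclusion
    rules; a True return excludes the patient (local exclusion policies
    differ between data sources, so they are configuration, not code).
    """
    study_end = pd.Timestamp(study_end)
    _check_columns(demographics, REQUIRED_DEMOGRAPHICS_COLS, "demographics")
    included = identify_af_cohort(
        hospital,
        dispensing,
        approval_dates,
        study_end=study_end,
        af_code_prefixes=af_code_prefixes,
    )
    demo = demographics.set_index("patient_id")
    disp_by_pt = dict(iter(dispensing.groupby("patient_id")))
    hosp_by_pt = dict(iter(hospital.groupby("patient_id")))
    empty_hosp = hospital.iloc[0:0]

    rows = []
    for pid in sorted(included):
        d = demo.loc[pid]
        pdisp = disp_by_pt[pid]
        pep = hosp_by_pt.get(pid, empty_hosp)
        skeleton = assign_index_and_end(pid, pdisp, d, study_end, approval_dates)
        if skeleton is None:
            continue
        idx = skeleton["index_date"]
        age = age_at(pd.Timestamp(d["birth_date"]), idx)
        codes = baseline_hospital_codes(pep, idx)
        meds = baseline_medication_profile(pdisp, idx, skeleton["index_drug"])
        row = {
            **skeleton,
            "sex": d["sex"],
            "age_at_index": age,
            "cha2ds2vasc": cha2ds2_vasc(d["sex"], age, codes, code_map),
            **meds,
            "polypharmacy": meds["n_distinct_drugs_baseline"] >= POLYPHARMACY_THRESHOLD,
        }
        if any(pred(row, pdisp, pep) for pred in extra_exclusions):
            logger.info("patient %s excluded by configured predicate", pid)
            continue
        rows.append(row)
    return pd.DataFrame(rows)
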