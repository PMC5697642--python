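"""Synthetic linked prescribing + hospital-episode data with known truth.

Emulates the linked structure of a national prescribing database and a
hospital-inpatient diagnosis dataset: every simulated patient has an AF
hospital episode before their first DOAC dispensing, a refill cadence
with configurable lateness/earliness, a latent exponential
discontinuation time, and a post-discontinuation pathway (reinitiate the
DOAC, switch lastingly to a vitamin K antagonist, or cease all oral
anticoagulation).  The latent trajectory is written to a separate
ground-truth table that the analysis pipeline never reads, so recovery
of discontinuation dates, pathways and adherence can be tested.

Key realisation choices (see the methods note for rationale):

* the next dispense date is the previous scheduled supply end plus a
  normal refill delay (may be negative = early), truncated so dispense
  dates are strictly increasing — this produces both gaps and
  stockpiling;
* the dispensed quantity is ``days covered x standard daily units`` and
  the final pack is trimmed at the patient's stopping day, so supply
  tiles the latent treatment period exactly and ground truth is
  recoverable without quantisation bias;
* a latent stop that leaves less than the admissible gap before the end
  of follow-up is unobservable by construction and is recorded as
  persisting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .vocab import APPROVAL_DATES, DOACS, STANDARD_DAILY_UNITS, doac_class

LN2 = math.log(2.0)

#: tablet strength written to the dispensing table, purely descriptive
_STRENGTH_MG = {"dabigatran": 150, "rivaroxaban": 20, "apixaban": 5, "warfarin": 3}

#: baseline co-medication repertoire: drug -> (drug_class, probability of
#: any use in the 6 months before the index date).  Sized so that the
#: simulated cohort shows the heavy polypharmacy of an elderly AF
#: population (~10 distinct drugs at baseline, ~90% with 5 or more).
DEFAULT_CONCOMITANT_DRUGS: dict[str, tuple[str, float]] = {
    "aspirin": ("aspirin", 0.342),
    "clopidogrel": ("antiplatelet", 0.111),
    "ibuprofen": ("NSAID", 0.061),
    "bisoprolol": ("other:beta_blocker", 0.665),
    "atenolol": ("other:beta_blocker", 0.20),
    "atorvastatin": ("other:statin", 0.40),
    "simvastatin": ("other:statin", 0.30),
    "ramipril": ("other:ras_agent", 0.35),
    "losartan": ("other:ras_agent", 0.25),
    "furosemide": ("other:diuretic", 0.40),
    "bendroflumethiazide": ("other:diuretic", 0.25),
    "amlodipine": ("other:ccb", 0.35),
    "digoxin": ("other:cardiac_glycoside", 0.30),
    "amiodarone": ("other:antiarrhythmic", 0.15),
    "isosorbide_mononitrate": ("other:nitrate", 0.20),
    "paracetamol": ("other:analgesic", 0.503),
    "codeine": ("other:analgesic", 0.20),
    "tramadol": ("other:analgesic", 0.12),
    "omeprazole": ("other:ppi", 0.40),
    "lansoprazole": ("other:ppi", 0.20),
    "levothyroxine": ("other:thyroid", 0.15),
    "metformin": ("other:antidiabetic", 0.14),
    "salbutamol": ("other:bronchodilator", 0.20),
    "citalopram": ("other:ssri", 0.15),
    "allopurinol": ("other:urate_lowering", 0.12),
    "tamsulosin": ("other:alpha_blocker", 0.12),
    "alendronate": ("other:bisphosphonate", 0.10),
    "clarithromycin": ("other:macrolide", 0.040),
    "itraconazole": ("other:antifungal", 0.012),
}

#: ICD-10 comorbidity blocks and their prevalence in the simulated cohort
DEFAULT_COMORBIDITY_PREVALENCES: dict[str, float] = {
    "I50": 0.187,  # congestive heart failure
    "I10": 0.383,  # essential hypertension
    "E11": 0.156,  # type 2 diabetes
    "I63": 0.155,  # cerebral infarction (prior stroke)
    "I70": 0.101,  # atherosclerosis (vascular disease)
}

PATHWAY_PERSIST = "persist"
PATHWAY_CEASE = "cease"
PATHWAY_REINITIATE = "reinitiate"
PATHWAY_SWITCH_VKA = "switch_vka"


@dataclass
class GeneratorConfig:
    """Study conditions for the simulator.

    Defaults emulate the structure of a national AF/DOAC cohort observed
    from September 2011 to June 2014: a drug mix dominated by
    rivaroxaban, 28-day packs, per-drug discontinuation medians of a few
    hundred days, roughly half of discontinuers reinitiating, and an
    elderly multimorbid population.
    """

    n_patients: int = 1000
    seed: int = 0
    study_start: pd.Timestamp = pd.Timestamp("2011-09-01")
    study_end: pd.Timestamp = pd.Timestamp("2014-06-30")
    drug_mix: dict[str, float] = field(
        default_factory=lambda: {
            "dabigatran": 0.188,
            "rivaroxaban": 0.610,
            "apixaban": 0.202,
        }
    )
    pack_days: dict[str, int] | int = 28
    #: mean/sd of days late per refill (negative mean = habitually early;
    #: the slightly early default produces the mild oversupply typical of
    #: repeat dispensing for chronic medication)
    refill_delay_mean: float = -2.0
    refill_delay_sd: float = 4.0
    #: between-patient sd of the habitual delay (adherence heterogeneity)
    patient_delay_sd: float = 3.0
    #: per-drug target median days on treatment; None = no discontinuation
    discontinuation_median_days: dict[str, float | None] | float | None = field(
        default_factory=lambda: {
            "dabigatran": 206.0,
            "rivaroxaban": 414.0,
            "apixaban": 393.0,
        }
    )
    reinit_prob: float = 0.483
    #: P(switch to VKA | discontinued and did not reinitiate)
    switch_to_vka_prob: float = 0.213
    #: the refill-gap rule the simulated pathways are realised against
    reference_gap_days: int = 28
    reinit_gap_max_days: int = 120
    mortality_rate: float = 0.08  # annual
    prior_vka_prob: float = 0.481
    female_prob: float = 0.458
    age_mean: float = 74.4
    age_sd: float = 11.3
    comorbidity_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCES)
    )
    concomitant_drugs: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONCOMITANT_DRUGS)
    )
    missing_instruction_prob: float = 0.10
    implausible_instruction_prob: float = 0.02
    #: True = everyone enters at study start; False = uniform enrolment
    #: between drug approval and study end
    enrol_at_start: bool = False
    approval_dates: dict[str, pd.Timestamp] = field(
        default_factory=lambda: dict(APPROVAL_DATES)
    )

    def __post_init__(self) -> None:
        self.study_start = pd.Timestamp(self.study_start)
        self.study_end = pd.Timestamp(self.study_end)
        self.validate()

    # -- helpers -----------------------------------------------------------
    def drugs(self) -> list[str]:
        return sorted(self.drug_mix)

    def pack_days_for(self, drug: str) -> int:
        if isinstance(self.pack_days, dict):
            return int(self.pack_days.get(drug, 28))
        return int(self.pack_days)

    def median_for(self, drug: str) -> float | None:
        m = self.discontinuation_median_days
        if isinstance(m, dict):
            m = m.get(drug)
        if m is None or (isinstance(m, float) and math.isinf(m)):
            return None
        return float(m)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if not self.study_start < self.study_end:
            raise ConfigurationError("study_start must precede study_end")
        total = sum(self.drug_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"drug_mix must sum to 1, got {total}")
        for drug, p in self.drug_mix.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"drug_mix[{drug}] not in [0, 1]")
            if drug not in DOACS:
                raise ConfigurationError(f"drug_mix contains unknown DOAC {drug!r}")
            if self.pack_days_for(drug) <= 0:
                raise ConfigurationError(f"pack_days[{drug}] must be positive")
            m = self.median_for(drug)
            if m is not None and m <= 0:
                raise ConfigurationError(
                    f"discontinuation_median_days[{drug}] must be positive"
                )
        for name in (
            "reinit_prob",
            "switch_to_vka_prob",
            "mortality_rate",
            "prior_vka_prob",
            "female_prob",
            "missing_instruction_prob",
            "implausible_instruction_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for code, p in self.comorbidity_prevalences.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(
                    f"comorbidity_prevalences[{code}] must be in [0, 1]"
                )
        if self.reference_gap_days <= 0:
            raise ConfigurationError("reference_gap_days must be positive")


@dataclass
class LinkedTables:
    dispensing: pd.DataFrame
    hospital: pd.DataFrame
    demographics: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        write_tables(self, outdir)


SCHEMA = {
    "dispensing.csv": [
        "patient_id",
        "dispense_date",
        "drug_name",
        "drug_class",
        "quantity",
        "strength_mg",
        "daily_dose_units",
    ],
    "hospital.csv": [
        "patient_id",
        "admission_date",
        "discharge_date",
        "diagnosis_codes",  # ';'-joined ICD-10, first = main position
    ],
    "demographics.csv": [
        "patient_id",
        "sex",
        "birth_date",
        "exit_date",
        "exit_reason",
    ],
    "latent_truth.csv": [
        "patient_id",
        "index_drug",
        "true_discontinuation_day",
        "true_pathway",
        "true_adherence_level",
    ],
}


# ---------------------------------------------------------------------------
# Refill mechanics


def _refill_run(rng, start_day, stop_day, pack, delay_mean, delay_sd):
    """Dispense (day, days_covered) pairs from start_day until coverage
    reaches stop_day.

    The next dispense date is the previous *assumed* supply end (the
    stockpiling carry-forward coverage end) plus a normal refill delay,
    truncated so dispense dates are strictly increasing; the final pack
    is trimmed so coverage ends exactly at ``stop_day``.  Early refills
    therefore keep a small bounded buffer of oversupply while late
    refills lose coverage days.  Returns the rows and the coverage end.
    """
    rows: list[tuple[int, int]] = []
    t = start_day
    cov_end = start_day
    while t < stop_day and cov_end < stop_day:
        cov_start = max(t, cov_end)
        cov = min(pack, stop_day - cov_start)
        if cov <= 0:
            break
        rows.append((t, cov))
        cov_end = cov_start + cov
        delay = delay_mean + (rng.normal(0.0, delay_sd) if delay_sd > 0 else 0.0)
        t_next = int(round(cov_end + delay))
        t = max(t_next, t + 1)
    return rows, cov_end


def inject_switch_and_reinit(rng, config, drug, disc_end_day, patient_end_day, delay_mean):
    """Realise the post-discontinuation pathway for one discontinuer.

    With probability ``reinit_prob`` the patient resumes the DOAC after a
    gap longer than the admissible gap; otherwise, with probability
    ``switch_to_vka_prob``, warfarin supply begins; otherwise nothing is
    appended (ceased all oral anticoagulation).  Requires enough room
    before ``patient_end_day`` for the gap to be observable.
    """
    gap_rule = config.reference_gap_days
    room = patient_end_day - disc_end_day
    if room <= gap_rule + 1:
        raise ValueError("pathway is unobservable: no admissible gap fits")
    rows: list[tuple[int, int, str]] = []
    if rng.random() < config.reinit_prob:
        gap = int(math.floor(rng.uniform(gap_rule + 1, config.reinit_gap_max_days)))
        # leave room for at least one day of resumed supply before follow-up ends
        start = disc_end_day + min(gap, room - 1)
        run, _ = _refill_run(
            rng,
            start,
            patient_end_day,
            config.pack_days_for(drug),
            delay_mean,
            config.refill_delay_sd,
        )
        rows.extend((d, c, drug) for d, c in run)
        return PATHWAY_REINITIATE, rows
    if rng.random() < config.switch_to_vka_prob:
        lead = int(math.floor(rng.uniform(5, max(6, min(60, room)))))
        start = disc_end_day + min(lead, room)
        run, _ = _refill_run(
            rng, start, patient_end_day, 28, delay_mean, config.refill_delay_sd
        )
        rows.extend((d, c, "warfarin") for d, c in run)
        return PATHWAY_SWITCH_VKA, rows
    return PATHWAY_CEASE, rows


# ---------------------------------------------------------------------------
# Main generator


def generate_linked_tables(config: GeneratorConfig) -> LinkedTables:
    """Generate linked dispensing/hospital/demographics tables plus the
    separate latent-truth table.  Identical configs give identical output."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    start_ts = config.study_start
    total_days = int((config.study_end - config.study_start).days)
    drugs = config.drugs()
    mix = np.array([config.drug_mix[d] for d in drugs])
    daily_mort_hazard = (
        -math.log(1.0 - config.mortality_rate) / 365.25
        if config.mortality_rate > 0
        else 0.0
    )

    disp_rows: list[dict] = []
    hosp_rows: list[dict] = []
    demo_rows: list[dict] = []
    truth_rows: list[dict] = []

    def add_dispensing(pid, day, drug, drug_class, days_covered):
        units = STANDARD_DAILY_UNITS.get(drug, 1.0)
        quantity = float(days_covered) * units
        u = rng.random()
        if u < config.missing_instruction_prob:
            instruction = np.nan
        elif u < config.missing_instruction_prob + config.implausible_instruction_prob:
            instruction = 0.0  # data-entry artefact; falls back to standard dosing
        else:
            instruction = units
        disp_rows.append(
            {
                "patient_id": pid,
                "dispense_date": start_ts + pd.Timedelta(days=int(day)),
                "drug_name": drug,
                "drug_class": drug_class,
                "quantity": quantity,
                "strength_mg": _STRENGTH_MG.get(drug, 0),
                "daily_dose_units": instruction,
            }
        )

    def add_episode(pid, admission_day, codes):
        stay = int(rng.integers(0, 9))
        disp_rows_day = start_ts + pd.Timedelta(days=int(admission_day))
        hosp_rows.append(
            {
                "patient_id": pid,
                "admission_date": disp_rows_day,
                "discharge_date": disp_rows_day + pd.Timedelta(days=stay),
                "diagnosis_codes": ";".join(codes),
            }
        )

    for i in range(config.n_patients):
        pid = f"SYN{i:06d}"
        drug = drugs[int(rng.choice(len(drugs), p=mix))]
        pack = config.pack_days_for(drug)
        approval_day = max(
            0, int((pd.Timestamp(config.approval_dates[drug]) - start_ts).days)
        )
        if config.enrol_at_start:
            index_day = approval_day
        else:
            index_day = int(rng.integers(approval_day, total_days))

        # demographics
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 30, 99))
        birth = start_ts + pd.Timedelta(days=index_day - int(round(age * 365.25)))
        sex = "female" if rng.random() < config.female_prob else "male"
        exit_day: int | None = None
        exit_reason = "none"
        if daily_mort_hazard > 0:
            death_offset = rng.exponential(1.0 / daily_mort_hazard)
            if index_day + death_offset <= total_days:
                exit_day = index_day + max(1, int(round(death_offset)))
                exit_reason = "death"
        patient_end_day = exit_day if exit_day is not None else total_days

        # latent discontinuation
        median = config.median_for(drug)
        true_disc: float | None = None
        if median is not None:
            true_disc = float(rng.exponential(median / LN2))

        delay_mean = config.refill_delay_mean + (
            rng.normal(0.0, config.patient_delay_sd)
            if config.patient_delay_sd > 0
            else 0.0
        )
        true_adherence = pack / max(pack + delay_mean, 1.0)

        # DOAC refills up to min(latent stop, end of follow-up)
        if true_disc is None:
            stop_day = patient_end_day
        else:
            stop_day = min(patient_end_day, index_day + max(1, int(round(true_disc))))
        run, cov_end = _refill_run(
            rng, index_day, stop_day, pack, delay_mean, config.refill_delay_sd
        )
        cls = doac_class(drug)
        for d, c in run:
            add_dispensing(pid, d, drug, cls, c)

        # post-discontinuation pathway, placed relative to the stockpiled
        # coverage end so the injected gap is what gap detection will see
        pathway = PATHWAY_PERSIST
        if true_disc is not None and stop_day < patient_end_day:
            if patient_end_day - cov_end > config.reference_gap_days + 1:
                pathway, extra = inject_switch_and_reinit(
                    rng, config, drug, cov_end, patient_end_day, delay_mean
                )
                for d, c, extra_drug in extra:
                    extra_cls = (
                        doac_class(extra_drug) if extra_drug in DOACS else "VKA"
                    )
                    add_dispensing(pid, d, extra_drug, extra_cls, c)
            # else: the run-out is not observable before follow-up ends

        # baseline co-medication (6 months pre-index)
        if rng.random() < config.prior_vka_prob:
            for _ in range(int(rng.integers(1, 4))):
                day = index_day - int(rng.integers(1, 184))
                add_dispensing(pid, day, "warfarin", "VKA", 28)
        for med in sorted(config.concomitant_drugs):
            med_class, prob = config.concomitant_drugs[med]
            if rng.random() < prob:
                for _ in range(int(rng.integers(1, 3))):
                    day = index_day - int(rng.integers(1, 184))
                    add_dispensing(pid, day, med, med_class, 28)

        # hospital episodes: AF before index, comorbidities in 5-year window
        af_day = index_day - int(rng.integers(1, 1827))
        add_episode(pid, af_day, [f"I48{int(rng.integers(0, 5))}"])
        for code in sorted(config.comorbidity_prevalences):
            if rng.random() < config.comorbidity_prevalences[code]:
                day = index_day - int(rng.integers(1, 1827))
                add_episode(pid, day, [code])
        if rng.random() < 0.3:  # unrelated admission noise
            day = index_day - int(rng.integers(1, 1827))
            add_episode(pid, day, ["J189"])

        demo_rows.append(
            {
                "patient_id": pid,
                "sex": sex,
                "birth_date": birth,
                "exit_date": (
                    start_ts + pd.Timedelta(days=exit_day)
                    if exit_day is not None
                    else pd.NaT
                ),
                "exit_reason": exit_reason,
            }
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "index_drug": drug,
                "true_discontinuation_day": (
                    np.nan if true_disc is None else true_disc
                ),
                "true_pathway": pathway,
                "true_adherence_level": true_adherence,
            }
        )

    dispensing = (
        pd.DataFrame(disp_rows)
        .sort_values(["patient_id", "dispense_date", "drug_name"], kind="stable")
        .reset_index(drop=True)
    )
    hospital = (
        pd.DataFrame(hosp_rows)
        .sort_values(["patient_id", "admission_date"], kind="stable")
        .reset_index(drop=True)
    )
    demographics = pd.DataFrame(demo_rows)
    truth = pd.DataFrame(truth_rows)
    return LinkedTables(dispensing, hospital, demographics, truth)


# ---------------------------------------------------------------------------
# I/O


def write_tables(tables: LinkedTables, outdir: str | Path) -> None:
    """Write the three analysis tables, the (pipeline-invisible) latent
    truth, and a schema file, all as CSV with ISO-8601 dates."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables.dispensing.to_csv(out / "dispensing.csv", index=False, date_format="%Y-%m-%d")
    tables.hospital.to_csv(out / "hospital.csv", index=False, date_format="%Y-%m-%d")
    tables.demographics.to_csv(
        out / "demographics.csv", index=False, date_format="%Y-%m-%d"
    )
    tables.truth.to_csv(out / "latent_truth.csv", index=False, date_format="%Y-%m-%d")
    (out / "schema.json").write_text(json.dumps(SCHEMA, indent=2))


def read_tables(indir: str | Path) -> LinkedTables:
    """Read tables written by :func:`write_tables` (truth is optional)."""
    p = Path(indir)
    dispensing = pd.read_csv(p / "dispensing.csv", parse_dates=["dispense_date"])
    hospital = pd.read_csv(
        p / "hospital.csv", parse_dates=["admission_date", "discharge_date"]
    )
    demographics = pd.read_csv(
        p / "demographics.csv", parse_dates=["birth_date", "exit_date"]
    )
    truth_path = p / "latent_truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
    return LinkedTables(dispensing, hospital, demographics, truth)
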