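"""Supply timelines and treatment-episode events from dispensing records.

A patient's dispensings are turned into a :class:`SupplyTimeline` — an
ordered sequence of supply intervals with assumed end dates — from which
refill-gap discontinuation, cessation, reinitiation, and the
post-discontinuation pathway are derived.

Two exposure scopes are supported:

``any_DOAC``
    supply from any direct oral anticoagulant counts, so switches between
    individual DOACs do not interrupt exposure;
``index_drug:<drug>``
    only the drug first prescribed counts.

Discontinuation uses the refill-gap method: the first gap of more than
``admissible_gap`` days without supply, following the assumed end of a
prescription, marks discontinuation, and the patient is censored after
that first event.  A terminal run-out counts only when the full admissible
gap is observable before the patient's end of follow-up; otherwise the
patient is censored still-on-treatment rather than misclassified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import NotComputableError
from .vocab import (
    CLASS_VKA,
    MAX_PLAUSIBLE_DAILY_UNITS,
    STANDARD_DAILY_UNITS,
    is_doac_class,
)

ANY_DOAC = "any_DOAC"
INDEX_DRUG_PREFIX = "index_drug:"

PATHWAY_ON_TREATMENT = "still_on_treatment"
PATHWAY_REINITIATED = "reinitiated"
PATHWAY_SWITCHED_VKA = "switched_vka"
PATHWAY_SWITCHED_DOAC = "switched_doac"  # index-drug scope only
PATHWAY_CEASED = "ceased_all_oac"


def index_drug_scope(drug: str) -> str:
    return INDEX_DRUG_PREFIX + drug


@dataclass(frozen=True)
class SupplyInterval:
    """One dispensing's contribution to the exposure timeline.

    ``coverage_start`` equals the dispense date unless stockpiling
    carry-forward pushed it later; ``assumed_end`` is exclusive
    (coverage_start + days_supply).
    """

    dispense_date: pd.Timestamp
    coverage_start: pd.Timestamp
    days_supply: float
    assumed_end: pd.Timestamp
    drug: str


@dataclass
class SupplyTimeline:
    patient_id: object
    scope: str
    intervals: list[SupplyInterval] = field(default_factory=list)
    window_start: pd.Timestamp | None = None
    window_end: pd.Timestamp | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def n_dispensings(self) -> int:
        return len(self.intervals)

    @property
    def total_days_supply(self) -> float:
        return sum(iv.days_supply for iv in self.intervals)

    def covers(self, when: pd.Timestamp, grace_days: float = 0.0) -> bool:
        """True if some supply interval covers ``when`` (+ optional grace)."""
        grace = pd.Timedelta(days=grace_days)
        return any(
            iv.coverage_start <= when <= iv.assumed_end + grace for iv in self.intervals
        )


@dataclass
class UtilisationEvents:
    """Per-patient discontinuation findings under a stated gap rule.

    Invariants: ``ceased or reinitiated`` each imply ``discontinued``;
    ``pathway == still_on_treatment`` iff not discontinued.
    """

    patient_id: object
    scope: str
    gap_days_rule: int
    discontinued: bool = False
    discontinuation_date: pd.Timestamp | None = None
    reinitiated: bool = False
    ceased: bool = False
    pathway: str = PATHWAY_ON_TREATMENT


def estimate_days_supply(
    quantity: float,
    daily_dose_units: float | None,
    drug: str,
    standard_dosing: dict[str, float] | None = None,
    max_daily_units: float = MAX_PLAUSIBLE_DAILY_UNITS,
) -> float:
    """Days of treatment covered by one dispensing.

    The prescriber's daily-dose instruction is used when present and
    plausible (0 < units <= ``max_daily_units``); otherwise the standard
    maintenance dosing for the drug.  A record with neither is rejected.
    """
    if quantity is None or not quantity > 0:
        raise NotComputableError(f"quantity must be positive, got {quantity!r}")
    standard = STANDARD_DAILY_UNITS if standard_dosing is None else standard_dosing
    if daily_dose_units is not None and not (
        isinstance(daily_dose_units, float) and math.isnan(daily_dose_units)
    ):
        if 0 < daily_dose_units <= max_daily_units:
            return float(quantity) / float(daily_dose_units)
    if drug not in standard:
        raise NotComputableError(
            f"no dose instruction and no standard dosing for drug {drug!r}"
        )
    return float(quantity) / float(standard[drug])


def in_scope(records: pd.DataFrame, scope: str) -> pd.Series:
    """Boolean mask of rows whose drug belongs to the exposure scope."""
    if scope == ANY_DOAC:
        return records["drug_class"].map(is_doac_class)
    if scope.startswith(INDEX_DRUG_PREFIX):
        drug = scope[len(INDEX_DRUG_PREFIX) :]
        return records["drug_name"] == drug
    raise ValueError(f"unknown scope {scope!r}")


def build_timeline(
    records: pd.DataFrame,
    scope: str,
    window: tuple[pd.Timestamp, pd.Timestamp],
    *,
    patient_id: object = None,
    stockpiling: bool = True,
    standard_dosing: dict[str, float] | None = None,
) -> SupplyTimeline:
    """Assemble a patient's supply timeline for one exposure scope.

    Records are filtered to the scope's drugs and the study window,
    same-day dispensings are merged (supplies summed) to avoid zero-length
    refill intervals, and assumed end dates are chained.  With stockpiling
    carry-forward on (the default) an early refill's coverage starts at the
    assumed end of the previous supply, so oversupply is credited forward;
    with it off, coverage starts at the dispense date and overlaps are
    simply discarded by the downstream gap scan.
    """
    start, end = window
    rec = records.loc[in_scope(records, scope)]
    rec = rec.loc[(rec["dispense_date"] >= start) & (rec["dispense_date"] <= end)]
    tl = SupplyTimeline(
        patient_id=patient_id, scope=scope, window_start=start, window_end=end
    )
    if rec.empty:
        return tl
    rec = rec.sort_values(["dispense_date", "drug_name"], kind="stable")

    # Per-record days supplied, then merge same-day rows by summing.
    merged: list[tuple[pd.Timestamp, float, str]] = []
    for row in rec.itertuples(index=False):
        days = estimate_days_supply(
            row.quantity,
            getattr(row, "daily_dose_units", None),
            row.drug_name,
            standard_dosing=standard_dosing,
        )
        if merged and merged[-1][0] == row.dispense_date:
            date0, days0, drug0 = merged[-1]
            merged[-1] = (date0, days0 + days, drug0)
        else:
            merged.append((row.dispense_date, days, row.drug_name))

    prev_end: pd.Timestamp | None = None
    for disp_date, days, drug in merged:
        cov_start = disp_date
        if stockpiling and prev_end is not None and prev_end > cov_start:
            cov_start = prev_end
        assumed_end = cov_start + pd.Timedelta(days=days)
        tl.intervals.append(
            SupplyInterval(
                dispense_date=disp_date,
                coverage_start=cov_start,
                days_supply=days,
                assumed_end=assumed_end,
                drug=drug,
            )
        )
        prev_end = assumed_end
    return tl


def detect_discontinuation(
    timeline: SupplyTimeline,
    patient_end: pd.Timestamp,
    admissible_gap: int = 28,
) -> UtilisationEvents:
    """Find the first refill gap exceeding the admissible gap.

    Scanning intervals in date order, the first occurrence of
    ``next coverage start - assumed_end > admissible_gap`` marks
    discontinuation at that assumed end; analysis is censored thereafter.
    A terminal run-out is a discontinuation only when
    ``patient_end - last assumed_end > admissible_gap`` — i.e. the full
    gap was observable before follow-up ended.
    """
    if not timeline.intervals:
        raise NotComputableError("cannot detect discontinuation on empty timeline")
    ev = UtilisationEvents(
        patient_id=timeline.patient_id,
        scope=timeline.scope,
        gap_days_rule=admissible_gap,
    )
    day = pd.Timedelta(days=1)
    ivs = timeline.intervals
    for prev, nxt in zip(ivs, ivs[1:]):
        gap = (nxt.coverage_start - prev.assumed_end) / day
        if gap > admissible_gap:
            ev.discontinued = True
            ev.discontinuation_date = prev.assumed_end
            return ev
    terminal_gap = (patient_end - ivs[-1].assumed_end) / day
    if terminal_gap > admissible_gap:
        ev.discontinued = True
        ev.discontinuation_date = ivs[-1].assumed_end
    return ev


def classify_pathway(
    events: UtilisationEvents, later_records: pd.DataFrame
) -> UtilisationEvents:
    """Classify what a discontinuer did next.

    ``later_records`` are the patient's dispensings (all drugs) strictly
    after the discontinuation date.  Any in-scope DOAC supply means the
    patient reinitiated, so they did not cease; otherwise a vitamin K
    antagonist dispensing means a lasting switch to VKA, and no further
    oral-anticoagulant supply at all means ceasing all OAC treatment.
    In the index-drug scope a later *different* DOAC is a switch between
    DOACs; in every non-reinitiation branch the patient ceased in-scope
    treatment.
    """
    if not events.discontinued:
        raise NotComputableError("pathway classification requires a discontinuation")
    after = later_records.loc[later_records["dispense_date"] > events.discontinuation_date]
    ev = replace(events)
    if in_scope(after, ev.scope).any():
        ev.reinitiated = True
        ev.ceased = False
        ev.pathway = PATHWAY_REINITIATED
        return ev
    ev.reinitiated = False
    ev.ceased = True
    if ev.scope != ANY_DOAC and after["drug_class"].map(is_doac_class).any():
        ev.pathway = PATHWAY_SWITCHED_DOAC
    elif (after["drug_class"] == CLASS_VKA).any():
        ev.pathway = PATHWAY_SWITCHED_VKA
    else:
        ev.pathway = PATHWAY_CEASED
    return ev


def patient_events(
    records: pd.DataFrame,
    scope: str,
    index_date: pd.Timestamp,
    end_date: pd.Timestamp,
    *,
    patient_id: object = None,
    admissible_gap: int = 28,
    stockpiling: bool = True,
    standard_dosing: dict[str, float] | None = None,
) -> tuple[SupplyTimeline, UtilisationEvents]:
    """Timeline + events for one patient under one scope and gap rule."""
    tl = build_timeline(
        records,
        scope,
        (index_date, end_date),
        patient_id=patient_id,
        stockpiling=stockpiling,
        standard_dosing=standard_dosing,
    )
    ev = detect_discontinuation(tl, end_date, admissible_gap=admissible_gap)
    if ev.discontinued:
        ev = classify_pathway(ev, records)
    return tl, ev


def cohort_events(
    dispensing: pd.DataFrame,
    cohort: pd.DataFrame,
    scope: str,
    *,
    admissible_gap: int = 28,
    stockpiling: bool = True,
    standard_dosing: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Events for every cohort patient, as a tidy audit table.

    ``scope`` may be ``any_DOAC`` or the literal ``index_drug``, in which
    case each patient's own first drug defines their scope.
    """
    grouped = dict(iter(dispensing.groupby("patient_id")))
    rows = []
    for c in cohort.itertuples(index=False):
        pt_scope = (
            index_drug_scope(c.index_drug) if scope == "index_drug" else scope
        )
        rec = grouped.get(c.patient_id)
        if rec is None:
            continue
        _, ev = patient_events(
            rec,
            pt_scope,
            c.index_date,
            c.end_date,
            patient_id=c.patient_id,
            admissible_gap=admissible_gap,
            stockpiling=stockpiling,
            standard_dosing=standard_dosing,
        )
        rows.append(
            {
                "patient_id": ev.patient_id,
                "scope": ev.scope,
                "index_drug": c.index_drug,
                "gap_days_rule": ev.gap_days_rule,
                "discontinued": ev.discontinued,
                "discontinuation_date": ev.discontinuation_date,
                "reinitiated": ev.reinitiated,
                "ceased": ev.ceased,
                "pathway": ev.pathway,
            }
        )
    return pd.DataFrame(rows)
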