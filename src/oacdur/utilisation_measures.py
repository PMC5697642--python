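"""The drug-utilisation measurement suite.

Implements a triangulated set of measures spanning all three phases of
drug utilisation — initiation, implementation, discontinuation:

* **Discontinuation rate** (refill-gap method, censoring after the first
  event) and **cessation rate** (allowing for reinitiation: only patients
  with no further in-scope supply through the study period count).
* **Persistence** at fixed anniversaries of initiation (anniversary
  method), which tolerates intermediary treatment interruptions.
* **Adherence**: medication refill adherence (MRA), compliance rate (CR)
  and the continuous, single-interval measure of medication availability
  (CSA), each a percentage that may exceed 100 (oversupply is
  meaningful and is not capped).

Adherence measures require at least two dispensings; patients below that
are excluded and the exclusion is counted.  Cohort-level values are
summarised as median and interquartile range plus the proportion of
patients strictly above a dichotomisation threshold (default 80%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NotComputableError, UndefinedRateError
from .exposure_episodes import SupplyTimeline

DAY = pd.Timedelta(days=1)


@dataclass
class MeasureSummary:
    measure: str
    scope: str
    n_denominator: int
    value: float  # rate, or median for adherence measures
    iqr: tuple[float, float] | None = None
    proportion_above_threshold: float | None = None
    threshold: float | None = None
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# Rates over per-patient events


def discontinuation_rate(events: pd.DataFrame) -> float:
    """Percentage of initiating patients with a refill-gap discontinuation."""
    if len(events) == 0:
        raise UndefinedRateError("discontinuation rate over empty cohort")
    return 100.0 * float(events["discontinued"].sum()) / len(events)


def cessation_rate(events: pd.DataFrame) -> float:
    """Percentage of initiating patients with no further in-scope supply."""
    if len(events) == 0:
        raise UndefinedRateError("cessation rate over empty cohort")
    return 100.0 * float(events["ceased"].sum()) / len(events)


# ---------------------------------------------------------------------------
# Persistence (anniversary method)


def anniversary_date(
    index_date: pd.Timestamp, months: int, mode: str = "calendar"
) -> pd.Timestamp:
    """The m-month anniversary of the index date.

    ``calendar`` adds calendar months with end-of-month clamping
    (Jan 31 + 1 month = Feb 28/29); ``days`` counts 183/365/548-style
    fixed day offsets (30.4375 days per month, rounded).
    """
    if mode == "calendar":
        return index_date + pd.DateOffset(months=months)
    if mode == "days":
        return index_date + pd.Timedelta(days=round(months * 365.25 / 12))
    raise ValueError(f"unknown anniversary mode {mode!r}")


def persistent_at(
    timeline: SupplyTimeline,
    index_date: pd.Timestamp,
    end_date: pd.Timestamp,
    months: int,
    *,
    grace_days: float = 0.0,
    mode: str = "calendar",
) -> bool | None:
    """Whether supply covers the anniversary date; None = insufficient follow-up."""
    ann = anniversary_date(index_date, months, mode)
    if end_date < ann:
        return None
    return timeline.covers(ann, grace_days=grace_days)


def persistence_at(
    timelines: dict[object, SupplyTimeline],
    cohort: pd.DataFrame,
    months: int,
    *,
    grace_days: float = 0.0,
    mode: str = "calendar",
) -> MeasureSummary:
    """Anniversary-method persistence: share of patients with sufficient
    follow-up whose drug supply covers the anniversary date."""
    n_num = n_den = 0
    scope = None
    for c in cohort.itertuples(index=False):
        tl = timelines.get(c.patient_id)
        if tl is None:
            continue
        scope = tl.scope
        res = persistent_at(
            tl, c.index_date, c.end_date, months, grace_days=grace_days, mode=mode
        )
        if res is None:
            continue
        n_den += 1
        n_num += bool(res)
    if n_den == 0:
        raise UndefinedRateError(f"no patient has {months} months of follow-up")
    return MeasureSummary(
        measure=f"persistence_{months}m",
        scope=scope or "",
        n_denominator=n_den,
        value=100.0 * n_num / n_den,
    )


# ---------------------------------------------------------------------------
# Per-patient adherence


def _require_two(timeline: SupplyTimeline, measure: str) -> None:
    if timeline.n_dispensings < 2:
        raise NotComputableError(
            f"{measure} requires >= 2 dispensings, got {timeline.n_dispensings}"
        )


def mra(timeline: SupplyTimeline, days_in_study: float) -> float:
    """Medication refill adherence: total days' supply over total days in
    study (index to individual end date), as a percentage.  Oversupply is
    not capped, so values above 100 indicate stockpiling."""
    _require_two(timeline, "MRA")
    if not days_in_study > 0:
        raise NotComputableError("MRA undefined for zero days in study")
    return 100.0 * timeline.total_days_supply / days_in_study


def cr(timeline: SupplyTimeline) -> float:
    """Compliance rate: supply excluding the last refill, over the days
    from first up to (but not including) the last refill."""
    _require_two(timeline, "CR")
    ivs = timeline.intervals
    span = (ivs[-1].dispense_date - ivs[0].dispense_date) / DAY
    if not span > 0:
        raise NotComputableError("CR undefined for zero first-to-last refill span")
    return 100.0 * (timeline.total_days_supply - ivs[-1].days_supply) / span


def csa_intervals(timeline: SupplyTimeline) -> list[float]:
    """Per-interval availability: each dispensing's days' supply over the
    days until the next dispensing.  The last dispensing opens no interval."""
    _require_two(timeline, "CSA")
    ivs = timeline.intervals
    out = []
    for cur, nxt in zip(ivs, ivs[1:]):
        length = (nxt.dispense_date - cur.dispense_date) / DAY
        out.append(100.0 * cur.days_supply / length)
    return out


def csa(timeline: SupplyTimeline) -> float:
    """Per-patient CSA summary: the median over the refill intervals."""
    return float(np.median(csa_intervals(timeline)))


# ---------------------------------------------------------------------------
# Windowed adherence ("0-6 months", "7-12 months", ...)


def windowed_adherence(
    timeline: SupplyTimeline,
    index_date: pd.Timestamp,
    end_date: pd.Timestamp,
    *,
    window_length: int = 183,
) -> pd.DataFrame:
    """Adherence recomputed inside consecutive fixed-length windows.

    Dispensings are assigned to windows by dispense date; the patient
    contributes a window only when follow-up covers it entirely, and each
    measure keeps its own preconditions within the window (MRA's
    denominator is the window length; CR/CSA need two dispensings in the
    window).  Measures that cannot be computed are NaN.
    """
    rows = []
    k = 0
    while True:
        w_start = index_date + pd.Timedelta(days=k * window_length)
        w_end = w_start + pd.Timedelta(days=window_length)
        if end_date < w_end:
            break
        sub = SupplyTimeline(
            patient_id=timeline.patient_id,
            scope=timeline.scope,
            intervals=[
                iv
                for iv in timeline.intervals
                if w_start <= iv.dispense_date < w_end
            ],
            window_start=w_start,
            window_end=w_end,
        )
        row = {
            "window": k,
            "window_start": w_start,
            "window_end": w_end,
            "n_dispensings": sub.n_dispensings,
            "mra": np.nan,
            "cr": np.nan,
            "csa": np.nan,
        }
        if sub.n_dispensings >= 2:
            row["mra"] = mra(sub, window_length)
            try:
                row["cr"] = cr(sub)
                row["csa"] = csa(sub)
            except NotComputableError:
                pass
        rows.append(row)
        k += 1
        if k > 1000:  # defensive: malformed dates
            break
    return pd.DataFrame(
        rows,
        columns=[
            "window",
            "window_start",
            "window_end",
            "n_dispensings",
            "mra",
            "cr",
            "csa",
        ],
    )


# ---------------------------------------------------------------------------
# Summaries


def dichotomise_and_summarise(
    values,
    *,
    threshold: float = 80.0,
    measure: str = "",
    scope: str = "",
    n_excluded: int = 0,
) -> MeasureSummary:
    """Median, IQR (linear-interpolation quartiles) and the proportion of
    values strictly above the adherence threshold."""
    arr = np.asarray([v for v in values if v is not None and not np.isnan(v)], float)
    if arr.size == 0:
        raise UndefinedRateError(f"no values to summarise for {measure or 'measure'}")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return MeasureSummary(
        measure=measure,
        scope=scope,
        n_denominator=int(arr.size),
        value=float(med),
        iqr=(float(q1), float(q3)),
        proportion_above_threshold=100.0 * float(np.mean(arr > threshold)),
        threshold=threshold,
        n_excluded=n_excluded,
    )
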