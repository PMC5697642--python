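"""Kaplan-Meier time to treatment discontinuation.

Events are coded 1 = discontinuation and 0 = still on treatment at end of
follow-up.  Follow-up is administratively capped per drug (by default one
year for apixaban, licensed latest, and two years for dabigatran and
rivaroxaban) on top of each patient's own end date.

The product-limit estimation itself is delegated to lifelines; this
module owns the input preparation, the conventions (median = smallest
time with S(t) <= 0.5; ties between events and censorings resolved with
events first, the product-limit standard) and a compact result object.
The 95% CI for the median comes from inverting the log-log (Greenwood)
pointwise confidence band at 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

from .errors import NotComputableError

logger = logging.getLogger(__name__)

DEFAULT_CENSORING_CAPS: dict[str, int] = {
    "apixaban": 365,
    "dabigatran": 730,
    "rivaroxaban": 730,
}


def prepare_survival_input(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    caps: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-patient (time, event) records for the KM estimator.

    ``time`` is days from index to the earliest of discontinuation, the
    patient's end date, and the per-drug administrative cap; ``event`` is
    1 only when the discontinuation occurs at or before both censoring
    bounds.  Records with non-positive time are dropped with a logged
    reason.
    """
    caps = DEFAULT_CENSORING_CAPS if caps is None else caps
    bad = [d for d, c in caps.items() if not c > 0]
    if bad:
        raise ValueError(f"non-positive censoring caps for: {bad}")
    merged = events.merge(
        cohort[["patient_id", "index_date", "end_date", "index_drug"]],
        on="patient_id",
        suffixes=("", "_cohort"),
    )
    rows = []
    day = pd.Timedelta(days=1)
    for r in merged.itertuples(index=False):
        cap = caps.get(r.index_drug)
        if cap is None:
            raise KeyError(f"no censoring cap configured for drug {r.index_drug!r}")
        censor_bound = min(float((r.end_date - r.index_date) / day), float(cap))
        if r.discontinued and not pd.isna(r.discontinuation_date):
            t_event = float((r.discontinuation_date - r.index_date) / day)
            if t_event <= censor_bound:
                time, event = t_event, 1
            else:
                time, event = censor_bound, 0
        else:
            time, event = censor_bound, 0
        if time <= 0:
            logger.warning(
                "patient %s dropped from survival input: non-positive time %s",
                r.patient_id,
                time,
            )
            continue
        rows.append({"patient_id": r.patient_id, "time": time, "event": event})
    return pd.DataFrame(rows, columns=["patient_id", "time", "event"])


@dataclass
class KMResult:
    """Product-limit estimate with Greenwood log-log confidence bands."""

    curve: pd.DataFrame  # time, at_risk, events, survival, ci_lower, ci_upper
    median: float | None  # None = not reached
    median_ci: tuple[float | None, float | None]
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return self.median is not None


def km_estimate(records: pd.DataFrame, alpha: float = 0.05) -> KMResult:
    """Kaplan-Meier estimate of time to discontinuation.

    The median is the smallest observed time with S(t) <= 0.5 and is
    reported as not reached when the curve never falls that low; its CI
    inverts the pointwise log-log band (Brookmeyer-Crowley style).
    """
    if len(records) == 0:
        raise NotComputableError("KM estimation requires at least one record")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(records["time"], event_observed=records["event"])

    surv = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    event_table = kmf.event_table
    curve = pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "at_risk": event_table["at_risk"].reindex(surv.index).to_numpy(),
            "events": event_table["observed"].reindex(surv.index).to_numpy(),
            "survival": surv.to_numpy(),
            "ci_lower": ci.iloc[:, 0].to_numpy(),
            "ci_upper": ci.iloc[:, 1].to_numpy(),
        }
    )

    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    med_ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(med_ci.iloc[0, 0]), float(med_ci.iloc[0, 1])
    median_ci = (None if np.isinf(lo) else lo, None if np.isinf(hi) else hi)

    return KMResult(
        curve=curve,
        median=median,
        median_ci=median_ci,
        n=int(len(records)),
        n_events=int(records["event"].sum()),
    )


def save_km_plot(results: dict[str, "KMResult"], path) -> None:
    """Step-plot the survival curves (one line per drug) to an image file.

    Requires matplotlib (optional dependency); pooled curves under the
    key ``all`` are drawn with a heavier line.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, res in sorted(results.items()):
        lw = 2.5 if name == "all" else 1.5
        ax.step(
            res.curve["time"],
            res.curve["survival"],
            where="post",
            label=f"{name} (n={res.n})",
            linewidth=lw,
        )
    ax.set_xlabel("days since first DOAC dispensing")
    ax.set_ylabel("proportion still on treatment")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def km_by_drug(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    caps: dict[str, int] | None = None,
) -> dict[str, KMResult]:
    """KM per index drug plus the pooled cohort under the key ``all``."""
    records = prepare_survival_input(events, cohort, caps)
    out: dict[str, KMResult] = {}
    if len(records):
        out["all"] = km_estimate(records)
    by_drug = cohort[["patient_id", "index_drug"]].merge(records, on="patient_id")
    for drug, grp in by_drug.groupby("index_drug"):
        out[str(drug)] = km_estimate(grp)
    return out
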