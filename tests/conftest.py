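"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's interval arithmetic:
possession is evaluated on a day-by-day grid with a supply "bank", and
adherence formulas are recomputed directly from raw (day, supply) pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oacdur.vocab import DOACS, STANDARD_DAILY_UNITS

T0 = pd.Timestamp("2013-01-01")


def ts(day: int) -> pd.Timestamp:
    return T0 + pd.Timedelta(days=day)


def make_dispensing(rows, patient_id="P1") -> pd.DataFrame:
    """Rows of (day, drug_name, quantity[, daily_dose_units]) -> table."""
    out = []
    for row in rows:
        day, drug, qty = row[0], row[1], row[2]
        units = row[3] if len(row) > 3 else STANDARD_DAILY_UNITS.get(drug, 1.0)
        if drug in DOACS:
            cls = "DOAC_" + drug
        elif drug == "warfarin":
            cls = "VKA"
        elif drug == "aspirin":
            cls = "aspirin"
        else:
            cls = "other:misc"
        out.append(
            {
                "patient_id": patient_id,
                "dispense_date": ts(day),
                "drug_name": drug,
                "drug_class": cls,
                "quantity": float(qty),
                "daily_dose_units": units,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Day-grid possession oracle


def day_grid_possession(dispensings, horizon=5000):
    """Boolean possession array from a supply bank walked day by day.

    ``dispensings``: iterable of (day, days_supply) with integer values.
    On a dispense day the supply is added to the bank; every day with a
    positive bank is covered and consumes one day of supply.  This is the
    day-grid equivalent of stockpiling carry-forward.
    """
    by_day: dict[int, int] = {}
    for day, supply in dispensings:
        by_day[day] = by_day.get(day, 0) + int(supply)
    first = min(by_day)
    covered = np.zeros(horizon, dtype=bool)
    bank = 0
    for d in range(first, horizon):
        bank += by_day.get(d, 0)
        if bank > 0:
            covered[d] = True
            bank -= 1
    assert bank == 0, "horizon too short for oracle"
    return covered


def day_grid_discontinuation(dispensings, end_day, gap):
    """First refill-gap discontinuation day from the possession grid.

    Returns the day coverage ended (the first uncovered day of the run),
    or None if no uncovered run longer than ``gap`` is fully observable
    before ``end_day``.
    """
    covered = day_grid_possession(dispensings)
    first = min(d for d, _ in dispensings)
    run_start = None
    for d in range(first, end_day):
        if covered[d]:
            if run_start is not None and d - run_start > gap:
                return run_start
            run_start = None
        else:
            if run_start is None:
                run_start = d
    if run_start is not None and end_day - run_start > gap:
        return run_start
    return None


# ---------------------------------------------------------------------------
# Direct-formula adherence oracles (independent arithmetic from raw pairs)


def oracle_mra(pairs, days_in_study):
    return 100.0 * sum(s for _, s in pairs) / days_in_study


def oracle_cr(pairs):
    pairs = sorted(pairs)
    total = sum(s for _, s in pairs)
    return 100.0 * (total - pairs[-1][1]) / (pairs[-1][0] - pairs[0][0])


def oracle_csa_values(pairs):
    pairs = sorted(pairs)
    return [
        100.0 * s / (d2 - d1)
        for (d1, s), (d2, _) in zip(pairs, pairs[1:])
    ]


# ---------------------------------------------------------------------------
# Independent product-limit estimator


def product_limit(times, events):
    """Hand-rolled Kaplan-Meier: (event_times, survival) arrays.

    At tied times events precede censorings.  Written independently of
    the survival module for cross-checking.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out_t, out_s = [], []
    for t in np.unique(times[events == 1]):
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_at_risk
        out_t.append(float(t))
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


@pytest.fixture
def perfect_config():
    """Zero-hazard, zero-delay study conditions: everyone enrols at the
    study start and refills exactly on time for 365 days."""
    from oacdur import GeneratorConfig

    return GeneratorConfig(
        n_patients=50,
        seed=11,
        study_start=pd.Timestamp("2012-03-01"),
        study_end=pd.Timestamp("2013-03-01"),
        drug_mix={"dabigatran": 0.4, "rivaroxaban": 0.4, "apixaban": 0.2},
        refill_delay_mean=0.0,
        refill_delay_sd=0.0,
        patient_delay_sd=0.0,
        discontinuation_median_days=None,
        mortality_rate=0.0,
        enrol_at_start=True,
        approval_dates={d: pd.Timestamp("2012-03-01") for d in DOACS},
    )
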