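"""The adherence measures on one hand-built refill history.

A patient collects 28-day supplies on days 0, 30 and 60 and is followed
for 120 days.  MRA spans the whole study period, CR the span between
first and last refill, and CSA each individual refill interval, so the
three measures answer subtly different questions about the same history.
"""

import pandas as pd

from oacdur import ANY_DOAC, build_timeline, cr, csa, csa_intervals, mra

T0 = pd.Timestamp("2013-01-01")
records = pd.DataFrame(
    {
        "patient_id": "P1",
        "dispense_date": [T0 + pd.Timedelta(days=d) for d in (0, 30, 60)],
        "drug_name": "rivaroxaban",
        "drug_class": "DOAC_rivaroxaban",
        "quantity": 28.0,  # 28 tablets, one per day
        "daily_dose_units": 1.0,
    }
)

timeline = build_timeline(records, ANY_DOAC, (T0, T0 + pd.Timedelta(days=120)))

print(f"MRA over 120 days in study: {mra(timeline, 120):6.2f} %")
print(f"CR  (first-to-last refill): {cr(timeline):6.2f} %")
print(f"CSA per interval:           {[round(v, 2) for v in csa_intervals(timeline)]}")
print(f"CSA patient summary:        {csa(timeline):6.2f} %")
# MRA = 100*84/120 = 70%: a third of the study period had no supply.
# CR = 100*(84-28)/60 = 93.3%: while refilling, the patient was nearly covered.
# CSA = 28/30 per interval = 93.3%: each refill came two days late.
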