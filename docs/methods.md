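# Methods

This note documents the models, conventions and design choices behind
`oacdur`: what each stage computes, why the defaults are what they are,
what the synthetic-data generator does and does not emulate, and the
numerical edge cases.

## Cohort construction

A patient enters the cohort when both hold:

1. **AF confirmed in secondary care**: at least one hospital episode
   carrying an ICD-10 code in the AF block (prefix `I48`, any diagnostic
   position, admissions from January 1997 onward), admitted on or before
   the first eligible DOAC dispensing. The code set is configuration,
   not code — real extracts can swap in a local code list.
2. **An eligible DOAC dispensing**: on or after the drug's approval date
   for stroke prevention in AF (defaults: dabigatran September 2011,
   rivaroxaban January 2012, apixaban January 2013) and on or before the
   study end.

The **index date** is the first eligible DOAC dispensing; same-day ties
between two DOACs are broken alphabetically by drug name (deterministic;
this affects only the index-drug label, and a test verifies that
either labelling yields identical any-DOAC-scope results). The **end
date** is death/deregistration or the study end, whichever is first.
Patients whose index postdates their end date are excluded with a
logged reason. Site-specific exclusion rules (e.g. short VTE-length
treatment courses) are supported as configurable predicates rather than
guessed at.

**Windows.** "6 months" is realised as 183 days and "5 years" as 1826
days, both half-open at the index date: a record exactly 183 days before
the index is inside the concomitant-medication window, a record on the
index date is not. CHA₂DS₂-VASc components come from hospital diagnoses
only (5-year window); the shipped ICD-10 component map (CHF `I50`,
`I11.0`; hypertension `I10`–`I15`; diabetes `E10`–`E14`; stroke/TIA
`I60`–`I64`, `G45`; vascular `I21`, `I22`, `I70`, `I73`) is an editable
default, since code sets differ between studies. Scoring: +1 each for
CHF, hypertension, diabetes, vascular disease, age 65–74 and female sex;
+2 each for age ≥ 75 and prior stroke/TIA.

## Supply timelines and episodes

Days' supply per dispensing is `quantity / daily_dose_units` when the
prescriber instruction is present and plausible (0 < units ≤ 10), else
`quantity / standard_daily_units` (dabigatran 2, rivaroxaban 1,
apixaban 2, warfarin 1). Same-day dispensings are merged with supplies
summed, which removes zero-length CSA intervals.

**Stockpiling carry-forward** (default on): the coverage of interval *k*
starts at `max(dispense_k, assumed_end_{k-1})`, so early-refill
oversupply is credited forward; with it off, coverage starts at the
dispense date and overlaps are ignored by the gap scan. Carry-forward is
the default because oversupply is evidently meaningful in dispensing
data (adherence medians above 100%) and because without it an early
refill can manufacture a spurious later gap. Both behaviours are exposed
for sensitivity analysis.

**Discontinuation** is the first occurrence, scanning in date order, of
`next coverage start − assumed_end > g` (strict inequality; *g* = 28 by
default, per "more than 28 days"), or a terminal run-out satisfying
`patient_end − last assumed_end > g`. The discontinuation date is the
assumed end of the last covered prescription, and the patient is
censored after this first event. A terminal run-out counts **only** when
the full admissible gap is observable before the end of follow-up;
otherwise the patient is censored still-on-treatment — this prevents
administrative censoring from masquerading as discontinuation, at the
price of never classifying a stop in the last *g* days of follow-up.

**Pathways.** Among a discontinuer's dispensings strictly after the
discontinuation date: any in-scope DOAC ⇒ reinitiated (not ceased);
otherwise the patient ceased in-scope treatment, subdivided into a
lasting switch to VKA (any VKA dispensing), a switch to a different DOAC
(index-drug scope only), or ceasing all oral anticoagulation. Cessation
therefore always implies discontinuation, and reinitiated + switched +
ceased partitions discontinuers exactly.

## Measures

- **MRA** uses the patient's full days in study (index to end date) as
  its denominator — not time to last refill — so a patient who stops
  early has a low MRA even if refills were punctual while they lasted.
  Oversupply is not capped.
- **CR** and **CSA** require ≥ 2 dispensings; excluded patients are
  counted and reported. The per-patient CSA summary is the median over
  refill intervals; the cohort-level value is the median of per-patient
  medians, with the pooled-intervals median also emitted
  (`csa_pooled_intervals`) since the literature is ambiguous about which
  is meant.
- **Persistence** anniversaries use calendar-month arithmetic with
  end-of-month clamping (Aug 31 + 6 months = Feb 28/29); a day-count
  mode is available for sensitivity. The anniversary grace defaults to
  0 days: supply must literally cover the date. Denominators shrink
  monotonically with later anniversaries (follow-up filter).
- **Windowed adherence** recomputes each measure inside consecutive
  183-day windows, assigning dispensings by dispense date; a patient
  contributes a window only if follow-up covers it entirely. MRA's
  windowed denominator is the window length.
- **Summaries**: medians and IQRs use linear-interpolation quartiles;
  the dichotomised share is *strictly* above the threshold (default
  80%).

## Kaplan–Meier

Survival input: time = min(discontinuation date, end date, index +
per-drug cap) − index; event = 1 only if the discontinuation is at or
before both censoring bounds. Caps default to 365 days for apixaban
(licensed latest) and 730 for dabigatran and rivaroxaban. Estimation is
delegated to lifelines (product-limit, Greenwood log-log 95% bands);
the median convention is the smallest observed time with S(t) ≤ 0.5,
reported "not reached" when the curve never falls that low, with the
median CI from inverting the pointwise band at 0.5
(Brookmeyer–Crowley style — the method is a documented package choice).
Tied events/censorings follow the product-limit standard (events first).

## The synthetic-data generator

The generator emulates the linked structure of a national dispensing
database and hospital-inpatient dataset for an AF/DOAC cohort observed
September 2011 – June 2014, with a hidden truth table the pipeline never
reads. Per patient:

- **Enrolment**: index drug drawn from the mix (defaults 0.188 / 0.610 /
  0.202 for dabigatran / rivaroxaban / apixaban, the composition of a
  national AF cohort of that era); index date uniform between the
  drug's approval and the study end (or fixed at the start, for
  controlled conditions). Age ~ N(74.4, 11.3) truncated to 30–99, 45.8%
  female, annual mortality 8% (exponential).
- **Latent discontinuation**: day drawn from an exponential with
  configurable per-drug median (defaults 206 / 414 / 393 days; the
  exponential is the simplest hazard with a closed-form median for
  recovery tests). `None` disables discontinuation entirely.
- **Refills**: the next dispense date is the previous *assumed* supply
  end — the stockpiling carry-forward coverage end — plus a normal delay
  (per-refill sd 4 days, per-patient habitual offset sd 3 days, mean −2:
  slightly early, producing the mild oversupply typical of repeat
  dispensing), truncated so dispense dates strictly increase. Quantities
  are `days covered × standard daily units`, so days'-supply estimation
  is exercised non-trivially; 10% of instructions are missing and 2%
  implausible (zero), exercising the standard-dosing fallback without
  corrupting the truth. The final pack is trimmed at the stopping bound
  (latent stop or end of follow-up), so supply tiles the treatment
  period exactly and the latent stop is recoverable without ±pack
  quantisation bias. Scheduling from the *assumed* end keeps the early-
  refill buffer bounded; a consequence is that whole-period MRA tops out
  near 100% while windowed MRA/CR/CSA exceed 100% under early refilling
  — the windowed-oversupply pattern seen in real dispensing data.
- **Pathways**: a discontinuer whose coverage ends with more than the
  admissible gap of observable follow-up remaining reinitiates with
  probability 0.483 (after a uniform 29–120-day gap), else switches
  lastingly to warfarin with probability 0.213, else ceases. These
  defaults reproduce a flow of roughly 48% reinitiation and 11% VKA
  switching among discontinuers. A latent stop too close to the end of
  follow-up is unobservable by construction and is recorded as
  persisting (stops with exactly gap+1 days of room are a sub-0.5%
  boundary case that may be observed as terminal discontinuation).
- **Linked records**: every patient has an AF episode (code `I48x`)
  strictly before the first DOAC dispensing; comorbidity episodes are
  drawn per ICD-10 block at configured prevalences (CHF 18.7%,
  hypertension 38.3%, diabetes 15.6%, stroke 15.5%, vascular 10.1%)
  uniformly within the 5-year pre-index window; baseline co-medication
  (including prior VKA at 48.1%) is sized so ~90% of patients have ≥ 5
  distinct drugs at baseline. No dispensing occurs after death.

**What the generator does not emulate** — and hence what passing tests
do and do not show: no DOAC-to-DOAC switching mid-treatment, no dose
changes or strength switches, no hospitalisation-induced refill gaps
(in-patient supply is unobserved in dispensing data), no repeated
discontinuation after reinitiation, no clinical outcomes, and no
seasonality or prescriber effects. Recovery results therefore validate
the measurement arithmetic and episode logic, not the realism of any
particular cohort's behaviour.

**Determinism**: all randomness flows from one root seed; identical
configs give byte-identical CSV output. Tables are written as CSV with
ISO-8601 dates plus a `schema.json`; the truth table is written
separately and is never read by the pipeline.

## Pipeline and problem sizes

`run_pipeline` computes every measure per scope (any-DOAC / index-drug),
per admissible gap (default 28 and 56 days, the sensitivity pair), per
drug and overall, and emits tidy CSVs plus a manifest (config hash,
seed, version). The default test and acceptance runs use cohorts of
500–2000 simulated patients — large enough for binomial tolerances of a
few percentage points and a KM-median sampling error well inside 5%,
small enough to run the whole suite in about a minute.

## Known limitations

- The refill-gap method is evaluated per exposure scope; in the
  index-drug scope a DOAC switcher is labelled `switched_doac` rather
  than folded into VKA switching.
- MRA's full-study denominator mixes implementation and persistence:
  discontinuers get low MRA regardless of refill punctuality. That is a
  property of the measure (and an argument for triangulation), not a
  bug.
- CHA₂DS₂-VASc from hospital records only under-ascertains conditions
  managed in primary care (e.g. hypertension); the simulated
  prevalences are *hospital-coded* prevalences.
- The median CI inverts pointwise bands; simultaneous bands would be
  wider.
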