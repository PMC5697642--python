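"""End-to-end orchestration: tables -> cohort -> episodes -> measures.

``run_pipeline`` produces a result bundle containing the baseline
(cohort) table, per-patient event tables for every requested scope and
admissible-gap length, a tidy measures table (one row per measure /
scope / drug / gap / window — the machine-readable analogue of a
published utilisation table), survival summaries with per-drug censoring
caps, and the pathway-flow counts partitioning discontinuers into
reinitiated / switched to VKA / ceased all OAC.

Everything is deterministic given the seed; outputs are plain CSV plus a
run manifest (config hash, seed, package version) for auditability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_builder import build_cohort
from .errors import ConfigurationError, UndefinedRateError
from .exposure_episodes import build_timeline, cohort_events, index_drug_scope
from .survival_analysis import DEFAULT_CENSORING_CAPS, km_by_drug
from .vocab import APPROVAL_DATES
from .synthetic_data import GeneratorConfig, LinkedTables, generate_linked_tables
from .utilisation_measures import (
    cessation_rate,
    cr,
    csa,
    csa_intervals,
    dichotomise_and_summarise,
    discontinuation_rate,
    mra,
    persistence_at,
    windowed_adherence,
)
from .errors import NotComputableError

logger = logging.getLogger(__name__)

SCOPES = ("any_DOAC", "index_drug")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig | None = None
    input_dir: str | None = None
    admissible_gap: int = 28
    sensitivity_gaps: tuple[int, ...] = (28, 56)
    scopes: tuple[str, ...] = SCOPES
    anniversary_months: tuple[int, ...] = (6, 12, 18)
    adherence_threshold: float = 80.0
    anniversary_grace_days: float = 0.0
    stockpiling: bool = True
    censoring_caps: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CENSORING_CAPS)
    )
    window_length_days: int = 183
    #: drug -> first approval date for the AF indication; None = use the
    #: generator's dates when simulating, else the built-in defaults
    approval_dates: dict | None = None
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.sensitivity_gaps):
            raise ConfigurationError("sensitivity_gaps must be positive")
        if self.admissible_gap <= 0:
            raise ConfigurationError("admissible_gap must be positive")
        months = list(self.anniversary_months)
        if any(m <= 0 for m in months) or months != sorted(months):
            raise ConfigurationError("anniversary_months must be positive and sorted")


@dataclass
class ResultBundle:
    cohort: pd.DataFrame
    events: pd.DataFrame  # all scopes x gaps, stacked
    measures: pd.DataFrame
    survival: pd.DataFrame
    pathway_flow: pd.DataFrame
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.cohort.to_csv(out / "cohort.csv", index=False, date_format="%Y-%m-%d")
        self.events.to_csv(out / "events.csv", index=False, date_format="%Y-%m-%d")
        self.measures.to_csv(out / "measures.csv", index=False)
        self.survival.to_csv(out / "survival.csv", index=False)
        self.pathway_flow.to_csv(out / "pathway_flow.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def pathway_flow(events: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of discontinuers by pathway.

    Percentages are over discontinuers and always partition them exactly
    (reinitiated + switched + ceased = discontinued).  Zero discontinuers
    yields an empty frame carrying an explicit marker column.
    """
    disc = events.loc[events["discontinued"]]
    if len(disc) == 0:
        return pd.DataFrame(
            columns=["pathway", "n", "percent"]
        ).assign(no_discontinuers=True)
    counts = disc.groupby("pathway").size().sort_index()
    out = pd.DataFrame(
        {
            "pathway": counts.index,
            "n": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / len(disc),
        }
    )
    return out.reset_index(drop=True)


def _patient_timelines(dispensing, cohort, scope, stockpiling):
    grouped = dict(iter(dispensing.groupby("patient_id")))
    timelines = {}
    for c in cohort.itertuples(index=False):
        pt_scope = index_drug_scope(c.index_drug) if scope == "index_drug" else scope
        rec = grouped.get(c.patient_id)
        if rec is None:
            continue
        timelines[c.patient_id] = build_timeline(
            rec,
            pt_scope,
            (c.index_date, c.end_date),
            patient_id=c.patient_id,
            stockpiling=stockpiling,
        )
    return timelines


def _summary_row(summary, *, drug, gap, window):
    return {
        "measure": summary.measure,
        "scope": summary.scope,
        "drug": drug,
        "gap_days": gap,
        "window": window,
        "n": summary.n_denominator,
        "value": summary.value,
        "iqr_lower": None if summary.iqr is None else summary.iqr[0],
        "iqr_upper": None if summary.iqr is None else summary.iqr[1],
        "proportion_above_threshold": summary.proportion_above_threshold,
        "n_excluded": summary.n_excluded,
    }


def _adherence_rows(timelines, cohort, scope, config):
    """MRA/CR/CSA summaries, overall and per index drug, plus windowed."""
    rows = []
    drug_groups = [("all", cohort)] + [
        (d, g) for d, g in cohort.groupby("index_drug")
    ]
    for drug, grp in drug_groups:
        per_patient = {"mra": [], "cr": [], "csa": []}
        pooled_csa_intervals: list[float] = []
        windowed: dict[int, dict[str, list[float]]] = {}
        n_excluded = 0
        for c in grp.itertuples(index=False):
            tl = timelines.get(c.patient_id)
            if tl is None or tl.n_dispensings < 2:
                n_excluded += 1
                continue
            per_patient["mra"].append(mra(tl, c.days_in_study))
            try:
                per_patient["cr"].append(cr(tl))
            except NotComputableError:
                pass
            per_patient["csa"].append(csa(tl))
            pooled_csa_intervals.extend(csa_intervals(tl))
            wdf = windowed_adherence(
                tl, c.index_date, c.end_date, window_length=config.window_length_days
            )
            for w in wdf.itertuples(index=False):
                slot = windowed.setdefault(w.window, {"mra": [], "cr": [], "csa": []})
                for m in ("mra", "cr", "csa"):
                    v = getattr(w, m)
                    if not pd.isna(v):
                        slot[m].append(v)
        for name, values in per_patient.items():
            if not values:
                continue
            s = dichotomise_and_summarise(
                values,
                threshold=config.adherence_threshold,
                measure=name,
                scope=scope,
                n_excluded=n_excluded,
            )
            rows.append(_summary_row(s, drug=drug, gap=None, window="overall"))
        if pooled_csa_intervals:
            s = dichotomise_and_summarise(
                pooled_csa_intervals,
                threshold=config.adherence_threshold,
                measure="csa_pooled_intervals",
                scope=scope,
                n_excluded=n_excluded,
            )
            rows.append(_summary_row(s, drug=drug, gap=None, window="overall"))
        for w in sorted(windowed):
            for name, values in windowed[w].items():
                if not values:
                    continue
                s = dichotomise_and_summarise(
                    values,
                    threshold=config.adherence_threshold,
                    measure=name,
                    scope=scope,
                )
                rows.append(_summary_row(s, drug=drug, gap=None, window=f"window_{w}"))
    return rows


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Run generate/load -> cohort -> episodes -> measures -> survival."""
    if config.generator is not None:
        tables = generate_linked_tables(config.generator)
        study_end = config.generator.study_end
        approvals = config.approval_dates or config.generator.approval_dates
    elif config.input_dir is not None:
        from .synthetic_data import read_tables

        tables = read_tables(config.input_dir)
        study_end = tables.dispensing["dispense_date"].max()
        approvals = config.approval_dates or APPROVAL_DATES
    else:
        raise ConfigurationError("config needs a generator or an input_dir")

    cohort = build_cohort(
        tables.dispensing,
        tables.hospital,
        tables.demographics,
        study_end,
        approval_dates=approvals,
    )
    if len(cohort) == 0:
        raise UndefinedRateError("empty cohort: no patient meets the inclusion rules")

    all_events = []
    measure_rows = []
    flow_frames = []
    survival_frames = []
    for scope in config.scopes:
        timelines = _patient_timelines(
            tables.dispensing, cohort, scope, config.stockpiling
        )
        # rates per admissible gap
        for gap in config.sensitivity_gaps:
            events = cohort_events(
                tables.dispensing,
                cohort,
                scope,
                admissible_gap=gap,
                stockpiling=config.stockpiling,
            )
            all_events.append(events)
            for drug, grp in [("all", events)] + list(events.groupby("index_drug")):
                measure_rows.append(
                    {
                        "measure": "discontinuation_rate",
                        "scope": scope,
                        "drug": drug,
                        "gap_days": gap,
                        "window": "overall",
                        "n": len(grp),
                        "value": discontinuation_rate(grp),
                        "iqr_lower": None,
                        "iqr_upper": None,
                        "proportion_above_threshold": None,
                        "n_excluded": 0,
                    }
                )
                measure_rows.append(
                    {
                        "measure": "cessation_rate",
                        "scope": scope,
                        "drug": drug,
                        "gap_days": gap,
                        "window": "overall",
                        "n": len(grp),
                        "value": cessation_rate(grp),
                        "iqr_lower": None,
                        "iqr_upper": None,
                        "proportion_above_threshold": None,
                        "n_excluded": 0,
                    }
                )
            if gap == config.admissible_gap:
                flow = pathway_flow(events).assign(scope=scope, gap_days=gap)
                flow_frames.append(flow)
                km = km_by_drug(events, cohort, config.censoring_caps)
                for drug, res in km.items():
                    survival_frames.append(
                        {
                            "scope": scope,
                            "drug": drug,
                            "gap_days": gap,
                            "n": res.n,
                            "n_events": res.n_events,
                            "median_days": res.median,
                            "median_ci_lower": res.median_ci[0],
                            "median_ci_upper": res.median_ci[1],
                        }
                    )
        # persistence + adherence (gap-independent)
        for months in config.anniversary_months:
            for drug, grp in [("all", cohort)] + list(cohort.groupby("index_drug")):
                try:
                    s = persistence_at(
                        timelines,
                        grp,
                        months,
                        grace_days=config.anniversary_grace_days,
                    )
                except UndefinedRateError:
                    continue
                s.scope = scope
                measure_rows.append(
                    _summary_row(s, drug=drug, gap=None, window="overall")
                )
        measure_rows.extend(_adherence_rows(timelines, cohort, scope, config))

    events_df = pd.concat(all_events, ignore_index=True)
    measures_df = pd.DataFrame(measure_rows)
    survival_df = pd.DataFrame(survival_frames)
    flow_df = (
        pd.concat(flow_frames, ignore_index=True) if flow_frames else pd.DataFrame()
    )

    manifest = {
        "package": "oacdur",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_cohort": int(len(cohort)),
        "scopes": list(config.scopes),
        "gaps": list(config.sensitivity_gaps),
    }
    bundle = ResultBundle(
        cohort=cohort,
        events=events_df,
        measures=measures_df,
        survival=survival_df,
        pathway_flow=flow_df,
        manifest=manifest,
    )
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (pd.Timestamp,)):
            return o.isoformat()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    # output_dir is run-local, not part of the scientific configuration
    fields = {
        k: v for k, v in dataclasses.asdict(config).items() if k != "output_dir"
    }
    payload = json.dumps(fields, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
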