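"""Supply timelines, days'-supply estimation, gap detection, pathways."""

import numpy as np
import pandas as pd
import pytest
from conftest import (
    day_grid_discontinuation,
    day_grid_possession,
    make_dispensing,
    ts,
)

from oacdur import (
    ANY_DOAC,
    build_timeline,
    classify_pathway,
    detect_discontinuation,
    estimate_days_supply,
    patient_events,
)
from oacdur.errors import NotComputableError
from oacdur.exposure_episodes import (
    PATHWAY_CEASED,
    PATHWAY_REINITIATED,
    PATHWAY_SWITCHED_VKA,
    index_drug_scope,
)


class TestEstimateDaysSupply:
    @pytest.mark.parametrize(
        "quantity, units, drug, expected",
        [
            (60, 2.0, "apixaban", 30.0),  # instruction used directly
            (28, None, "rivaroxaban", 28.0),  # standard dosing 1/day
            (56, 0.0, "dabigatran", 28.0),  # implausible 0 -> standard 2/day
            (56, np.nan, "dabigatran", 28.0),  # missing -> standard
            (28, 50.0, "rivaroxaban", 28.0),  # implausibly high -> standard
        ],
    )
    def test_instruction_and_fallback(self, quantity, units, drug, expected):
        assert estimate_days_supply(quantity, units, drug) == expected

    def test_unknown_drug_without_instruction_rejected(self):
        with pytest.raises(NotComputableError):
            estimate_days_supply(28, None, "unobtainium")

    def test_nonpositive_quantity_rejected(self):
        with pytest.raises(NotComputableError):
            estimate_days_supply(0, 1.0, "rivaroxaban")


class TestBuildTimeline:
    def test_back_to_back_supplies(self):
        disp = make_dispensing([(0, "rivaroxaban", 28), (28, "rivaroxaban", 28)])
        tl = build_timeline(disp, ANY_DOAC, (ts(0), ts(200)))
        assert tl.intervals[-1].assumed_end == ts(56)
        assert tl.intervals[1].coverage_start == ts(28)

    def test_early_refill_carries_forward(self):
        disp = make_dispensing([(0, "rivaroxaban", 28), (20, "rivaroxaban", 28)])
        tl = build_timeline(disp, ANY_DOAC, (ts(0), ts(200)))
        assert tl.intervals[1].coverage_start == ts(28)
        assert tl.intervals[1].assumed_end == ts(56)

    def test_stockpiling_off_uses_dispense_date(self):
        disp = make_dispensing([(0, "rivaroxaban", 28), (20, "rivaroxaban", 28)])
        tl = build_timeline(disp, ANY_DOAC, (ts(0), ts(200)), stockpiling=False)
        assert tl.intervals[1].coverage_start == ts(20)
        assert tl.intervals[1].assumed_end == ts(48)

    def test_same_day_dispensings_merged(self):
        disp = make_dispensing(
            [(0, "rivaroxaban", 28), (0, "rivaroxaban", 28), (56, "rivaroxaban", 28)]
        )
        tl = build_timeline(disp, ANY_DOAC, (ts(0), ts(200)))
        assert tl.n_dispensings == 2
        assert tl.intervals[0].days_supply == 56

    def test_scope_filters_drugs(self):
        disp = make_dispensing(
            [(0, "rivaroxaban", 28), (10, "warfarin", 28), (30, "apixaban", 56)]
        )
        any_tl = build_timeline(disp, ANY_DOAC, (ts(0), ts(200)))
        idx_tl = build_timeline(
            disp, index_drug_scope("rivaroxaban"), (ts(0), ts(200))
        )
        assert any_tl.n_dispensings == 2
        assert idx_tl.n_dispensings == 1

    def test_total_covered_days_matches_day_grid(self):
        """Interval arithmetic agrees with the brute-force possession grid."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 7))
            days = np.cumsum(rng.integers(1, 60, size=n))
            supplies = rng.integers(1, 60, size=n)
            pairs = list(zip(days.tolist(), supplies.tolist()))
            disp = make_dispensing([(d, "rivaroxaban", s) for d, s in pairs])
            tl = build_timeline(disp, ANY_DOAC, (ts(0), ts(10000)))
            interval_days = sum(
                (iv.assumed_end - iv.coverage_start) / pd.Timedelta(days=1)
                for iv in tl.intervals
            )
            assert interval_days == day_grid_possession(pairs, horizon=20000).sum()


class TestDetectDiscontinuation:
    def make_events(self, rows, end_day, gap=28):
        disp = make_dispensing(rows)
        tl = build_timeline(disp, ANY_DOAC, (ts(0), ts(end_day)))
        return detect_discontinuation(tl, ts(end_day), admissible_gap=gap)

    def test_gap_of_29_is_discontinuation(self):
        # supply ends day 100, next dispense day 129
        ev = self.make_events(
            [(0, "rivaroxaban", 100), (129, "rivaroxaban", 28)], 400
        )
        assert ev.discontinued and ev.discontinuation_date == ts(100)

    def test_gap_of_exactly_28_is_not(self):
        ev = self.make_events(
            [(0, "rivaroxaban", 100), (128, "rivaroxaban", 28)], 400
        )
        # terminal run-out after day 156 still counts, so check the date
        assert ev.discontinuation_date != ts(100)

    def test_terminal_runout_shortly_before_end_is_censored(self):
        ev = self.make_events([(0, "rivaroxaban", 100)], 110)
        assert not ev.discontinued

    def test_terminal_runout_with_observable_gap_counts(self):
        ev = self.make_events([(0, "rivaroxaban", 100)], 129)
        assert ev.discontinued and ev.discontinuation_date == ts(100)

    def test_empty_timeline_rejected(self):
        disp = make_dispensing([(0, "warfarin", 28)])  # out of scope
        tl = build_timeline(disp, ANY_DOAC, (ts(0), ts(100)))
        with pytest.raises(NotComputableError):
            detect_discontinuation(tl, ts(100))

    def test_agrees_with_day_grid_oracle(self):
        """Gap detection matches the brute-force possession scan on 300
        random mini-timelines."""
        rng = np.random.default_rng(7)
        n_checked = 0
        for _ in range(300):
            n = int(rng.integers(1, 7))
            days = np.concatenate([[0], np.cumsum(rng.integers(1, 70, size=n - 1))])
            supplies = rng.integers(1, 50, size=n)
            end_day = int(days[-1] + supplies[-1] + rng.integers(0, 80))
            gap = int(rng.choice([14, 28, 56]))
            pairs = list(zip(days.tolist(), supplies.tolist()))
            ev = self.make_events(
                [(d, "rivaroxaban", s) for d, s in pairs], end_day, gap=gap
            )
            oracle_day = day_grid_discontinuation(pairs, end_day, gap)
            if oracle_day is None:
                assert not ev.discontinued
            else:
                assert ev.discontinued
                assert (ev.discontinuation_date - ts(0)) / pd.Timedelta(days=1) == oracle_day
                n_checked += 1
        assert n_checked > 50  # the sweep actually exercised discontinuations

    def test_gap_rule_monotonicity(self):
        """Discontinued under a 56-day gap implies discontinued under 28."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(1, 7))
            days = np.concatenate([[0], np.cumsum(rng.integers(1, 90, size=n - 1))])
            supplies = rng.integers(1, 50, size=n)
            pairs = [(int(d), "rivaroxaban", int(s)) for d, s in zip(days, supplies)]
            end_day = int(days[-1] + supplies[-1] + rng.integers(0, 100))
            ev28 = self.make_events(pairs, end_day, gap=28)
            ev56 = self.make_events(pairs, end_day, gap=56)
            if ev56.discontinued:
                assert ev28.discontinued


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    gaps=st.lists(st.integers(1, 80), min_size=0, max_size=5),
    supplies=st.lists(st.integers(1, 50), min_size=1, max_size=6),
    tail=st.integers(0, 90),
    gap_rule=st.sampled_from([14, 28, 56]),
)
def test_gap_detection_matches_day_grid_property(gaps, supplies, tail, gap_rule):
    """Property: on any integer mini-timeline, interval-arithmetic gap
    detection and the brute-force possession grid find the same (non-)
    discontinuation and the same date."""
    n = min(len(supplies), len(gaps) + 1)
    days = [0]
    for g in gaps[: n - 1]:
        days.append(days[-1] + g)
    pairs = list(zip(days, supplies[:n]))
    end_day = days[-1] + supplies[n - 1] + tail
    disp = make_dispensing([(d, "rivaroxaban", s) for d, s in pairs])
    tl = build_timeline(disp, ANY_DOAC, (ts(0), ts(end_day)))
    ev = detect_discontinuation(tl, ts(end_day), admissible_gap=gap_rule)
    oracle_day = day_grid_discontinuation(pairs, end_day, gap_rule)
    if oracle_day is None:
        assert not ev.discontinued
    else:
        assert ev.discontinued
        assert (ev.discontinuation_date - ts(0)) / pd.Timedelta(days=1) == oracle_day


class TestClassifyPathway:
    def base_records(self):
        return [(0, "rivaroxaban", 100)]

    def run(self, extra, scope=ANY_DOAC, end_day=400):
        disp = make_dispensing(self.base_records() + extra)
        _, ev = patient_events(disp, scope, ts(0), ts(end_day))
        return ev

    def test_later_doac_means_reinitiated(self):
        ev = self.run([(200, "apixaban", 56)])
        assert ev.pathway == PATHWAY_REINITIATED
        assert ev.reinitiated and not ev.ceased

    def test_later_vka_means_lasting_switch(self):
        ev = self.run([(130, "warfarin", 28)])
        assert ev.pathway == PATHWAY_SWITCHED_VKA
        assert ev.ceased  # switching counts towards cessation

    def test_nothing_after_means_ceased_all_oac(self):
        ev = self.run([])
        assert ev.pathway == PATHWAY_CEASED and ev.ceased

    def test_vka_then_doac_is_reinitiation(self):
        ev = self.run([(130, "warfarin", 28), (250, "rivaroxaban", 28)])
        assert ev.pathway == PATHWAY_REINITIATED

    def test_continuous_single_drug_nondiscontinued_in_both_scopes(self):
        rows = [(0, "rivaroxaban", 28), (28, "rivaroxaban", 28), (56, "rivaroxaban", 300)]
        disp = make_dispensing(rows)
        for scope in (ANY_DOAC, index_drug_scope("rivaroxaban")):
            _, ev = patient_events(disp, scope, ts(0), ts(360))
            assert not ev.discontinued
            assert ev.pathway == "still_on_treatment"

    def test_events_invariants(self):
        for extra in ([], [(150, "apixaban", 28)], [(140, "warfarin", 28)]):
            ev = self.run(extra)
            assert ev.discontinued
            if ev.ceased or ev.reinitiated:
                assert ev.discontinued
            assert (ev.pathway == "still_on_treatment") == (not ev.discontinued)
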