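"""Unit and property tests for the undesiredness classifiers."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import slot_simulator, static_brute_force
from undesired.classify import (
    BirthHistory,
    ChildRecord,
    FertilityPreference,
    SequenceError,
    aggregate_excess,
    apply_eligibility_filters,
    classify_children_sequential,
    classify_mother_static,
    classify_population,
    events_from_records,
)


def all_preferences(max_total: int):
    for b in range(max_total + 1):
        for g in range(max_total + 1 - b):
            for n in range(max_total + 1 - b - g):
                yield (b, g, n)


class TestStaticClassifier:
    def test_worked_example_state_not_excessive(self):
        # ideal 2 boys + 1 girl + 1 either; living 3 boys + 1 girl
        pref = FertilityPreference(2, 1, 1)
        hist = BirthHistory(
            [ChildRecord(i, "M") for i in (1, 2, 3)] + [ChildRecord(4, "F")]
        )
        flags = classify_mother_static(pref, hist)
        assert flags.as_dict() == {
            "excess_boys": 0,
            "excess_girls": 0,
            "excess_dual": 0,
            "excess_parity": 0,
        }

    def test_zero_ideal_single_child(self):
        pref = FertilityPreference(0, 0, 0)
        hist = BirthHistory([ChildRecord(1, "M")])
        flags = classify_mother_static(pref, hist)
        assert flags.excess_parity == 1
        assert flags.excess_boys == 1
        assert flags.excess_girls == 0

    def test_exhaustive_against_brute_force(self):
        for pref_t in all_preferences(4):
            pref = FertilityPreference(*pref_t)
            for boys in range(6):
                for girls in range(6 - boys):
                    hist = BirthHistory(
                        [ChildRecord(i + 1, "M") for i in range(boys)]
                        + [ChildRecord(boys + i + 1, "F") for i in range(girls)]
                    )
                    got = classify_mother_static(pref, hist)
                    want = static_brute_force(pref_t, boys, girls)
                    assert got.excess_parity == want["excess_parity"]
                    assert got.excess_boys == want["excess_boys"]
                    assert got.excess_girls == want["excess_girls"]

    def test_dual_rules(self):
        pref = FertilityPreference(0, 0, 0)
        hist = BirthHistory([ChildRecord(1, "M"), ChildRecord(2, "F")])
        both = classify_mother_static(pref, hist, "both_sexes")
        sp = classify_mother_static(pref, hist, "sex_and_parity")
        assert both.excess_dual == 1  # both sexes exceed a zero ideal
        assert sp.excess_dual == 1
        with pytest.raises(ValueError, match="dual_rule"):
            classify_mother_static(pref, hist, "bogus")

    def test_dead_children_not_counted(self):
        pref = FertilityPreference(1, 0, 0)
        hist = BirthHistory([ChildRecord(1, "M", alive=False), ChildRecord(2, "M")])
        assert classify_mother_static(pref, hist).excess_boys == 0


class TestSequentialClassifier:
    def test_worked_example(self):
        pref = FertilityPreference(2, 1, 1)
        events = [("birth", "M")] * 4 + [("death", 1), ("birth", "F"), ("birth", "M")]
        flags = classify_children_sequential(pref, events)
        assert [(f.gender_excess, f.parity_excess) for f in flags] == [
            (0, 0), (0, 0), (0, 0), (1, 0), (0, 0), (1, 1),
        ]
        assert flags[5].dual_excess == 1

    def test_under_quota(self):
        flags = classify_children_sequential(
            FertilityPreference(9, 0, 0), [("birth", "M")]
        )
        assert flags[0].gender_excess == 0
        assert flags[0].parity_excess == 0

    def test_death_of_unknown_child(self):
        with pytest.raises(SequenceError):
            classify_children_sequential(
                FertilityPreference(1, 1, 0), [("birth", "M"), ("death", 7)]
            )
        with pytest.raises(SequenceError):
            classify_children_sequential(
                FertilityPreference(1, 1, 0),
                [("birth", "M"), ("death", 1), ("death", 1)],
            )

    def test_exhaustive_no_death_oracle(self):
        for pref_t in all_preferences(4):
            pref = FertilityPreference(*pref_t)
            for k in range(6):
                for sexes in itertools.product("MF", repeat=k):
                    events = [("birth", s) for s in sexes]
                    got = classify_children_sequential(pref, events)
                    want = slot_simulator(pref_t, events)
                    assert [
                        (f.gender_excess, f.parity_excess) for f in got
                    ] == want, (pref_t, sexes)

    def test_random_death_sequences_oracle(self, rng):
        prefs = list(all_preferences(4))
        for _ in range(300):
            pref_t = prefs[rng.integers(len(prefs))]
            events = []
            born = []
            for _ in range(rng.integers(1, 7)):
                if born and rng.random() < 0.3:
                    dead = born.pop(rng.integers(len(born)))
                    events.append(("death", dead))
                else:
                    order = sum(1 for e in events if e[0] == "birth") + 1
                    events.append(("birth", "M" if rng.random() < 0.5 else "F"))
                    born.append(order)
            got = classify_children_sequential(FertilityPreference(*pref_t), events)
            want = slot_simulator(pref_t, events)
            assert [(f.gender_excess, f.parity_excess) for f in got] == want

    @given(
        b=st.integers(0, 3),
        g=st.integers(0, 3),
        n=st.integers(0, 3),
        sexes=st.lists(st.sampled_from("MF"), max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_parity_count_property_no_deaths(self, b, g, n, sexes):
        pref = FertilityPreference(b, g, n)
        flags = classify_children_sequential(pref, [("birth", s) for s in sexes])
        n_parity = sum(f.parity_excess for f in flags)
        assert n_parity == max(0, len(sexes) - pref.total)

    @given(
        b=st.integers(0, 3),
        g=st.integers(0, 3),
        n=st.integers(0, 3),
        sexes=st.lists(st.sampled_from("MF"), min_size=1, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotonicity_no_deaths(self, b, g, n, sexes):
        pref = FertilityPreference(b, g, n)
        events = [("birth", s) for s in sexes]
        full = classify_children_sequential(pref, events)
        prefix = classify_children_sequential(pref, events[:-1])
        assert full[: len(prefix)] == prefix

    @given(
        b=st.integers(0, 3),
        g=st.integers(0, 3),
        n=st.integers(0, 3),
        sexes=st.lists(st.sampled_from("MF"), max_size=8),
    )
    @settings(max_examples=150, deadline=None)
    def test_static_sequential_consistency_no_deaths(self, b, g, n, sexes):
        pref = FertilityPreference(b, g, n)
        flags = classify_children_sequential(pref, [("birth", s) for s in sexes])
        hist = BirthHistory(
            [ChildRecord(i + 1, s) for i, s in enumerate(sexes)]
        )
        static = classify_mother_static(pref, hist)
        assert (sum(f.parity_excess for f in flags) > 0) == bool(static.excess_parity)
        # gender flags count un-slotted children under greedy consumption
        # (the static per-sex inequality lets both sexes reuse the same
        # either-gender slot, so it is a lower bound, not an equivalence)
        oracle = slot_simulator((b, g, n), [("birth", s) for s in sexes])
        assert sum(f.gender_excess for f in flags) == sum(gf for gf, _ in oracle)
        if static.excess_boys:
            assert sum(f.excess_boys for f in flags) > 0
        if static.excess_girls:
            assert sum(f.excess_girls for f in flags) > 0

    def test_missing_sex_counts_for_parity_only(self):
        pref = FertilityPreference(0, 0, 1)
        flags = classify_children_sequential(
            pref, [("birth", "U"), ("birth", "U")]
        )
        assert [(f.gender_excess, f.parity_excess) for f in flags] == [(0, 0), (0, 1)]

    def test_missing_sex_population_warns(self):
        mothers = pd.DataFrame(
            {"mother_id": [1], "B_m": [0], "G_m": [0], "N_m": [1], "C_m": [1]}
        )
        children = pd.DataFrame(
            {
                "mother_id": [1, 1],
                "birth_order": [1, 2],
                "sex": [np.nan, "M"],
                "alive": [1, 1],
            }
        )
        with pytest.warns(UserWarning, match="missing sex"):
            flags = classify_population(mothers, children)
        child = flags[flags["level"] == "child"].set_index("birth_order")
        assert child.loc[2, "excess_parity"] == 1  # unknown-sex child counted
        assert child.loc[1, "excess_boys"] == 0

    def test_purity(self):
        pref = FertilityPreference(1, 1, 1)
        events = [("birth", "M"), ("birth", "M"), ("birth", "F")]
        assert classify_children_sequential(pref, events) == classify_children_sequential(
            pref, events
        )


class TestEventsFromRecords:
    def test_death_after_defaults_to_own_birth(self):
        df = pd.DataFrame(
            {
                "birth_order": [1, 2],
                "sex": ["M", "F"],
                "alive": [0, 1],
                "death_after": [np.nan, np.nan],
            }
        )
        assert events_from_records(df) == [
            ("birth", "M"),
            ("death", 1),
            ("birth", "F"),
        ]

    def test_delayed_death(self):
        df = pd.DataFrame(
            {
                "birth_order": [1, 2, 3],
                "sex": ["M", "M", "F"],
                "alive": [0, 1, 1],
                "death_after": [2.0, np.nan, np.nan],
            }
        )
        assert events_from_records(df) == [
            ("birth", "M"),
            ("birth", "M"),
            ("death", 1),
            ("birth", "F"),
        ]


class TestEligibilityFilters:
    def _tables(self, c_ms):
        mothers = pd.DataFrame(
            {
                "mother_id": range(1, len(c_ms) + 1),
                "B_m": [0] * len(c_ms),
                "G_m": [0] * len(c_ms),
                "N_m": c_ms,
                "C_m": c_ms,
            }
        )
        children = pd.DataFrame(
            {
                "mother_id": range(1, len(c_ms) + 1),
                "birth_order": [1] * len(c_ms),
                "sex": ["M"] * len(c_ms),
                "alive": [1] * len(c_ms),
            }
        )
        return mothers, children

    def test_ideal_over_nine_removed(self):
        mothers, children = self._tables([10, 3])
        m, c, report = apply_eligibility_filters(mothers, children)
        assert len(m) == 1 and report["dropped_ideal_gt9"] == 1
        assert set(c["mother_id"]) == {2}

    def test_noop_when_all_eligible(self):
        mothers, children = self._tables([2, 3, 9])
        m, c, report = apply_eligibility_filters(mothers, children)
        assert len(m) == 3 and len(c) == 3
        assert report["dropped_ideal_gt9"] == 0

    def test_counts_reconcile(self):
        mothers, children = self._tables([1, 10, 2, 11, 3])
        m, _, report = apply_eligibility_filters(mothers, children)
        assert len(m) == 3
        assert report["input_mothers"] == report["output_mothers"] + report[
            "dropped_ideal_gt9"
        ] + report["dropped_ideal_missing"]

    def test_missing_column_raises(self):
        mothers, children = self._tables([1])
        with pytest.raises(ValueError, match="alive"):
            apply_eligibility_filters(mothers, children.drop(columns=["alive"]))

    def test_child_age_window(self):
        mothers, children = self._tables([2, 2])
        children["age_ch"] = [3, 6]
        _, c, report = apply_eligibility_filters(mothers, children)
        assert len(c) == 1 and report["dropped_child_age_gt_window"] == 1


class TestAggregate:
    def _flags(self, parity_flags):
        rows = [
            {
                "mother_id": 1,
                "birth_order": i + 1,
                "level": "child",
                "excess_boys": 0,
                "excess_girls": 0,
                "excess_dual": 0,
                "excess_parity": f,
            }
            for i, f in enumerate(parity_flags)
        ]
        rows.append(
            {
                "mother_id": 1,
                "birth_order": 0,
                "level": "mother",
                "excess_boys": 0,
                "excess_girls": 0,
                "excess_dual": 0,
                "excess_parity": int(any(parity_flags)),
            }
        )
        return pd.DataFrame(rows)

    def test_none_flagged(self):
        agg = aggregate_excess(self._flags([0, 0, 0]))
        assert all(v["percent"] == 0.0 for v in agg["child_level"].values())

    def test_two_of_eight(self):
        agg = aggregate_excess(self._flags([1, 1, 0, 0, 0, 0, 0, 0]))
        assert agg["child_level"]["excess_parity"]["percent"] == 25.0
        assert agg["mother_level"]["excess_parity"]["percent"] == 100.0

    def test_percentages_in_range(self, small_population):
        flags = classify_population(small_population.mothers, small_population.children)
        agg = aggregate_excess(flags)
        for level in ("child_level", "mother_level"):
            for v in agg[level].values():
                assert 0.0 <= v["percent"] <= 100.0


def test_population_permutation_invariance(small_population):
    mothers = small_population.mothers
    children = small_population.children
    flags = classify_population(mothers, children)
    relabel = {m: 100000 + m for m in mothers["mother_id"]}
    m2 = mothers.copy()
    m2["mother_id"] = m2["mother_id"].map(relabel)
    c2 = children.copy()
    c2["mother_id"] = c2["mother_id"].map(relabel)
    flags2 = classify_population(m2.iloc[::-1], c2)
    a = flags.assign(mother_id=flags["mother_id"].map(relabel)).sort_values(
        ["mother_id", "level", "birth_order"]
    )
    b = flags2.sort_values(["mother_id", "level", "birth_order"])
    pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))
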