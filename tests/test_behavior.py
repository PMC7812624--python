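"""Turn segmentation, composites, ICC and weighted kappa."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadsync.behavior import (
    composite_scores,
    icc,
    segment_turns,
    weighted_kappa,
)
from dyadsync.montage_io import CodingEvent, ValidationError

from conftest import event, log_of


def reference_segmentation(events, max_gap_ms=3000.0):
    """Independent single-pass turn segmentation used as the test oracle."""
    turns = []
    for ev in events:
        if turns and ev.speaker == turns[-1]["speaker"] \
                and ev.onset_ms - turns[-1]["end"] <= max_gap_ms:
            turns[-1]["end"] = max(turns[-1]["end"], ev.offset_ms)
            turns[-1]["n"] += 1
        else:
            turns.append({"speaker": ev.speaker, "start": ev.onset_ms,
                          "end": ev.offset_ms, "n": 1})
    kinds = []
    for a, b in zip(turns, turns[1:]):
        gap = b["start"] - a["end"]
        if gap < 0:
            kinds.append("overlap")
        elif gap > max_gap_ms:
            kinds.append("long_pause_break")
        elif b["speaker"] != a["speaker"]:
            kinds.append("alternation")
        else:
            kinds.append("same_speaker_continuation")
    return turns, kinds


class TestSegmentTurns:
    # hand-traced fixtures: (events, expected turn count, transition kinds)
    FIXTURES = [
        # clean alternation, 200 ms gap
        ([("mother", 0, 1000), ("child", 1200, 2000)],
         2, ["alternation"]),
        # same speaker, 500 ms gap -> merged into one turn
        ([("mother", 0, 1000), ("mother", 1500, 2000)],
         1, []),
        # overlap: child starts 200 ms before mother finishes
        ([("mother", 0, 1000), ("child", 800, 1800)],
         2, ["overlap"]),
        # long pause (> 3000 ms) breaks the chain without alternation
        ([("mother", 0, 1000), ("child", 4500, 5000)],
         2, ["long_pause_break"]),
        # same speaker after a long pause -> two turns, no alternation
        ([("mother", 0, 1000), ("mother", 4200, 5000)],
         2, ["long_pause_break"]),
        # triple: alternation then merge
        ([("mother", 0, 800), ("child", 900, 1500), ("child", 1600, 2100)],
         2, ["alternation"]),
    ]

    @pytest.mark.parametrize("events,n_turns,kinds", FIXTURES)
    def test_hand_traced_fixtures(self, events, n_turns, kinds):
        seq = segment_turns(log_of([event(*e) for e in events]))
        assert len(seq.turns) == n_turns
        assert [t.kind for t in seq.transitions] == kinds

    def test_overlap_duration_recorded(self):
        seq = segment_turns(log_of([event("mother", 0, 1000),
                                    event("child", 800, 1800)]))
        assert seq.transitions[0].gap_ms == -200
        assert seq.total_overlap_ms == 200

    def test_alternation_gap_value(self):
        seq = segment_turns(log_of([event("mother", 0, 1000),
                                    event("child", 1200, 2000)]))
        assert seq.transitions[0].gap_ms == 200

    def test_matches_reference_on_random_logs(self, rng):
        speakers = np.array(["mother", "child"])
        for _ in range(30):
            t = 0.0
            events = []
            for _k in range(rng.integers(2, 25)):
                dur = rng.uniform(200, 2500)
                events.append(CodingEvent(speakers[rng.integers(2)],
                                          t, t + dur, "vocalization"))
                t += dur + rng.uniform(-150, 4000)
                t = max(t, events[-1].onset_ms + 1)
            events.sort(key=lambda e: (e.onset_ms, e.offset_ms))
            seq = segment_turns(log_of(events))
            ref_turns, ref_kinds = reference_segmentation(events)
            assert len(seq.turns) == len(ref_turns)
            assert [t.kind for t in seq.transitions] == ref_kinds
            assert [t.n_utterances for t in seq.turns] \
                == [r["n"] for r in ref_turns]

    @given(st.lists(st.tuples(st.booleans(),
                              st.floats(min_value=100, max_value=2500),
                              st.floats(min_value=-200, max_value=4000)),
                    min_size=1, max_size=15))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_reference_equivalence_property(self, steps):
        """For any event stream, segmentation matches the independent
        single-pass reference implementation."""
        t = 0.0
        events = []
        for is_mother, dur, gap in steps:
            events.append(CodingEvent("mother" if is_mother else "child",
                                      t, t + dur, "vocalization"))
            t = max(t + dur + gap, events[-1].onset_ms + 1.0)
        events.sort(key=lambda e: (e.onset_ms, e.offset_ms))
        seq = segment_turns(log_of(events))
        ref_turns, ref_kinds = reference_segmentation(events)
        assert len(seq.turns) == len(ref_turns)
        assert [tr.kind for tr in seq.transitions] == ref_kinds

    def test_turn_count_invariant_to_event_splitting(self):
        whole = log_of([event("mother", 0, 1000), event("child", 1200, 2000)])
        split = log_of([event("mother", 0, 500), event("mother", 500, 1000),
                        event("child", 1200, 2000)])
        assert len(segment_turns(whole).turns) \
            == len(segment_turns(split).turns)


class TestCompositeScores:
    def test_turn_taking_equal_weighted_mean(self):
        events = [event("mother", i * 1000, i * 1000 + 500,
                        "alternating_turn") for i in range(10)]
        events += [event("mother", 20000 + i * 1000, 20000 + i * 1000 + 500,
                         "long_turn") for i in range(4)]
        scores = composite_scores(log_of(events))
        assert scores.turn_taking == 7.0  # mean(10, 4)

    def test_empty_log_gives_zero_composites(self):
        scores = composite_scores(log_of([]))
        assert scores.turn_taking == scores.relevance == 0.0
        assert scores.contingency == scores.intrusiveness == 0.0
        assert scores.mean_turn_duration_ms == 0.0

    def test_intrusiveness_mean_of_three_subcounts(self):
        events = [event("mother", 0, 400, "interrupts"),
                  event("child", 500, 900, "interrupts"),
                  event("mother", 1000, 1400, "simultaneous")]
        scores = composite_scores(log_of(events))
        assert scores.intrusiveness == 1.0  # mean(0 fails, 2, 1)

    def test_negative_subcategories_signed(self):
        events = [event("mother", 0, 400, "relevant"),
                  event("child", 500, 900, "relevant"),
                  event("mother", 1000, 1400, "irrelevant"),
                  event("child", 1500, 1900, "noncontingent")]
        scores = composite_scores(log_of(events))
        assert scores.relevance == pytest.approx((2 - 1) / 2)
        assert scores.contingency == pytest.approx((0 - 1) / 2)

    def test_row_order_invariance(self, rng):
        events = [event("mother", i * 600, i * 600 + 400,
                        ["relevant", "contingent", "alternating_turn"][i % 3])
                  for i in range(9)]
        shuffled = list(events)
        rng.shuffle(shuffled)
        a = composite_scores(log_of(events))
        b = composite_scores(log_of(shuffled))
        assert a.to_row() == b.to_row()


class TestICC:
    def test_identical_raters_give_one(self):
        x = np.column_stack([np.arange(6.0), np.arange(6.0)])
        value, ms = icc(x)
        assert value == pytest.approx(1.0)

    def test_matches_anova_oracle_and_pingouin(self):
        ratings = np.array([[9., 2., 5., 8.],
                            [6., 1., 3., 2.],
                            [8., 4., 6., 8.],
                            [7., 1., 2., 6.],
                            [10., 5., 6., 9.],
                            [6., 2., 4., 7.]])
        value, ms = icc(ratings)
        import pandas as pd
        import pingouin as pg

        n, k = ratings.shape
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": ratings.ravel()})
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score")
        expected = table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert value == pytest.approx(expected, abs=1e-6)

    def test_constant_offset_penalized(self):
        base = np.arange(8.0)
        value, _ = icc(np.column_stack([base, base + 2.0]))
        assert value < 1.0

    def test_zero_variance_undefined(self):
        with pytest.raises(ValidationError, match="undefined"):
            icc(np.ones((4, 2)))

    def test_table_shape_validated(self):
        with pytest.raises(ValidationError):
            icc(np.ones((1, 2)))


class TestWeightedKappa:
    def test_identical_ratings_give_one(self):
        r = np.array([0, 1, 2, 1, 0, 2])
        assert weighted_kappa(r, r) == pytest.approx(1.0)

    def test_matches_confusion_matrix_oracle_and_sklearn(self, rng):
        r1 = rng.integers(0, 3, size=60)
        r2 = np.clip(r1 + rng.integers(-1, 2, size=60), 0, 2)
        got = weighted_kappa(r1, r2)
        # brute-force from the confusion matrix
        k = 3
        obs = np.zeros((k, k))
        for a, b in zip(r1, r2):
            obs[a, b] += 1
        obs /= obs.sum()
        exp = np.outer(obs.sum(1), obs.sum(0))
        w = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        oracle = 1 - (w * obs).sum() / (w * exp).sum()
        assert got == pytest.approx(oracle, abs=1e-12)
        from sklearn.metrics import cohen_kappa_score

        assert got == pytest.approx(
            cohen_kappa_score(r1, r2, weights="linear"), abs=1e-12)

    def test_independent_ratings_near_zero(self, rng):
        r1 = rng.integers(0, 4, size=10000)
        r2 = rng.integers(0, 4, size=10000)
        assert abs(weighted_kappa(r1, r2)) < 0.05

    def test_single_category_undefined(self):
        with pytest.raises(ValidationError, match="single category"):
            weighted_kappa(np.zeros(5, int), np.zeros(5, int))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            weighted_kappa([0, 1], [0, 1, 2])
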