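"""Conversation-pattern scoring: turn segmentation, category composites,
and inter-rater reliability statistics.

A *turn* is one person's speech bounded by pauses or by the other person's
speech; a speaker change with a gap of at most 3000 ms counts as an
alternation, while longer pauses break the chain without alternation credit.
Per-dyad composites average the (equally weighted) counts of each category's
sub-codes: turn-taking from alternating and long turns; relevance from
relevant minus irrelevant turns; contingency from contingent minus
noncontingent utterances; intrusiveness from failures to leave response
time, interruptions and simultaneous speech.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dyadsync.montage_io import CodingLog, ValidationError

TURN_TAKING_CODES = ("alternating_turn", "long_turn")
RELEVANCE_CODES = {"relevant": +1, "irrelevant": -1}
CONTINGENCY_CODES = {"contingent": +1, "noncontingent": -1}
INTRUSIVENESS_CODES = ("no_time_for_response", "interrupts", "simultaneous")


@dataclass(frozen=True)
class Turn:
    speaker: str
    start_ms: float
    end_ms: float
    n_utterances: int


@dataclass(frozen=True)
class Transition:
    gap_ms: float
    kind: str  # alternation | same_speaker_continuation | long_pause_break | overlap


@dataclass
class TurnSequence:
    turns: list[Turn] = field(default_factory=list)
    transitions: list[Transition] = field(default_factory=list)

    @property
    def n_alternations(self) -> int:
        return sum(t.kind == "alternation" for t in self.transitions)

    @property
    def mean_turn_duration_ms(self) -> float:
        if not self.turns:
            return 0.0
        return float(np.mean([t.end_ms - t.start_ms for t in self.turns]))

    @property
    def total_overlap_ms(self) -> float:
        return float(sum(-t.gap_ms for t in self.transitions
                         if t.kind == "overlap"))


@dataclass
class DyadScores:
    """Per-dyad conversation composites and turn/overlap durations."""

    dyad_id: str
    turn_taking: float
    relevance: float
    contingency: float
    intrusiveness: float
    mean_turn_duration_ms: float
    total_overlap_ms: float
    counts: dict[str, int] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"dyad_id": self.dyad_id, "turn_taking": self.turn_taking,
               "relevance": self.relevance, "contingency": self.contingency,
               "intrusiveness": self.intrusiveness,
               "mean_turn_duration_ms": self.mean_turn_duration_ms,
               "total_overlap_ms": self.total_overlap_ms}
        row.update({f"n_{k}": v for k, v in sorted(self.counts.items())})
        return row


def scores_frame(scores: list[DyadScores]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in scores])


def segment_turns(log: CodingLog, max_gap_ms: float = 3000.0,
                  min_gap_ms: float = 0.0) -> TurnSequence:
    """Chunk utterance events into turns and classify transitions.

    Consecutive events (in onset order) by the same speaker with a gap of at
    most ``max_gap_ms`` merge into one turn.  Between turns: a speaker change
    with gap in [``min_gap_ms``, ``max_gap_ms``] is an ``alternation``; a gap
    beyond ``max_gap_ms`` is a ``long_pause_break``; the partner starting
    before the current turn ends is an ``overlap`` (negative gap records the
    overlap duration).
    """
    events = log.events
    if not events:
        return TurnSequence()
    turns: list[Turn] = []
    cur_speaker = events[0].speaker
    cur_start = events[0].onset_ms
    cur_end = events[0].offset_ms
    cur_n = 1
    for ev in events[1:]:
        gap = ev.onset_ms - cur_end
        if ev.speaker == cur_speaker and gap <= max_gap_ms:
            cur_end = max(cur_end, ev.offset_ms)
            cur_n += 1
        else:
            turns.append(Turn(cur_speaker, cur_start, cur_end, cur_n))
            cur_speaker, cur_start, cur_end, cur_n = \
                ev.speaker, ev.onset_ms, ev.offset_ms, 1
    turns.append(Turn(cur_speaker, cur_start, cur_end, cur_n))

    transitions: list[Transition] = []
    for prev, nxt in zip(turns, turns[1:]):
        gap = nxt.start_ms - prev.end_ms
        if gap < 0:
            kind = "overlap"
        elif gap > max_gap_ms:
            kind = "long_pause_break"
        elif nxt.speaker != prev.speaker and gap >= min_gap_ms:
            kind = "alternation"
        else:
            kind = "same_speaker_continuation"
        transitions.append(Transition(gap_ms=gap, kind=kind))
    return TurnSequence(turns=turns, transitions=transitions)


def composite_scores(log: CodingLog, turns: TurnSequence | None = None,
                     ) -> DyadScores:
    """Equally weighted composite per category from Table-style code counts.

    Sign convention (documented, switch by negating counts upstream): the
    explicitly negative sub-codes (irrelevant, noncontingent) enter with a
    minus so that higher composites mean more cohesive conversation.
    """
    if turns is None:
        turns = segment_turns(log)
    counts = log.counts_by_code()
    turn_taking = float(np.mean([counts[c] for c in TURN_TAKING_CODES]))
    relevance = float(np.mean([sign * counts[c]
                               for c, sign in RELEVANCE_CODES.items()]))
    contingency = float(np.mean([sign * counts[c]
                                 for c, sign in CONTINGENCY_CODES.items()]))
    intrusiveness = float(np.mean([counts[c] for c in INTRUSIVENESS_CODES]))
    return DyadScores(dyad_id=log.dyad_id, turn_taking=turn_taking,
                      relevance=relevance, contingency=contingency,
                      intrusiveness=intrusiveness,
                      mean_turn_duration_ms=turns.mean_turn_duration_ms,
                      total_overlap_ms=turns.total_overlap_ms,
                      counts=counts)


def icc(ratings: np.ndarray, form: str = "two_way_random_absolute_single",
        ) -> tuple[float, dict[str, float]]:
    """Intraclass correlation ICC(2,1) from the two-way ANOVA decomposition.

    ``ratings`` is an (n_subjects, k_raters) table without missing cells.
    Returns the coefficient and the mean squares (rows = subjects,
    columns = raters, error) used to compute it.
    """
    if form != "two_way_random_absolute_single":
        raise ValueError(f"unsupported ICC form {form!r}")
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("need >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValidationError("ICC table must be complete")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_total == 0:
        raise ValidationError("ICC undefined: zero total variance")
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = (msr - mse) / denom
    return float(value), {"ms_rows": float(msr), "ms_cols": float(msc),
                          "ms_error": float(mse)}


def weighted_kappa(r1, r2, weights: str = "linear",
                   categories=None) -> float:
    """Cohen's weighted kappa for two ordinal rating vectors.

    ``kappa_w = 1 - sum(w o) / sum(w e)`` with linear (or quadratic)
    disagreement weights and the marginal-product expected matrix.
    """
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValidationError("rating vectors must be 1-D and equal length")
    if categories is None:
        categories = np.unique(np.concatenate([r1, r2]))
    categories = np.asarray(categories)
    k = len(categories)
    if k < 2:
        raise ValidationError(
            "weighted kappa undefined: a single category present")
    lookup = {c: i for i, c in enumerate(categories)}
    i1 = np.array([lookup[v] for v in r1])
    i2 = np.array([lookup[v] for v in r2])
    obs = np.zeros((k, k))
    np.add.at(obs, (i1, i2), 1.0)
    obs /= obs.sum()
    marg1 = obs.sum(axis=1)
    marg2 = obs.sum(axis=0)
    exp = np.outer(marg1, marg2)
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    dis = np.abs(ii - jj).astype(float)
    if weights == "quadratic":
        dis = dis ** 2
    elif weights != "linear":
        raise ValueError(f"unknown weighting {weights!r}")
    denom = (dis * exp).sum()
    if denom == 0:
        raise ValidationError("weighted kappa undefined: degenerate margins")
    return float(1.0 - (dis * obs).sum() / denom)
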