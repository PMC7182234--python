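"""Transformed Brier scoring and paired per-event score differences.

The score of a probability forecast T_k against a binary outcome D_k is

    s_k = 100 - 100 * (D_k - T_k)^2

and a method's score is the mean of s_k over the K scored events. This is an
affine transform of the raw Brier score (S = 100 * (1 - Brier)), so it is
strictly proper: in expectation it is maximized only by reporting the true
probability. 100 is a perfect forecast, 0 the worst possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .aggregation import extremise
from .data import Dataset
from .errors import ValidationError


@dataclass
class ScoreReport:
    """Per-event and summary transformed Brier scores for one method."""

    method: str
    per_event_scores: dict[str, float]
    by_difficulty: dict[int, float] = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.per_event_scores)

    @property
    def mean_score(self) -> float:
        return float(np.mean(list(self.per_event_scores.values())))


def per_event_score(forecast: float, outcome: int) -> float:
    """100 - 100 * squared error; invariant to relabeling
    (p, outcome=1) <-> (1-p, outcome=0)."""
    return 100.0 - 100.0 * (outcome - forecast) ** 2


def transformed_brier(forecasts, outcomes, difficulties=None,
                      method: str = "") -> ScoreReport:
    """Score a map event_id -> probability against event_id -> outcome.

    Every forecast event must have an outcome; ``difficulties`` (optional
    map event_id -> tier) enables the per-tier summary.
    """
    if len(forecasts) == 0:
        raise ValidationError("need at least one event to score")
    missing = set(forecasts) - set(outcomes)
    if missing:
        raise ValidationError(
            f"no outcome for events: {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    scores = {
        ev: per_event_score(float(forecasts[ev]), int(outcomes[ev]))
        for ev in forecasts
    }
    report = ScoreReport(method=method, per_event_scores=scores)
    if difficulties is not None:
        tiers = {}
        for ev, s in scores.items():
            tiers.setdefault(int(difficulties[ev]), []).append(s)
        report.by_difficulty = {t: float(np.mean(v)) for t, v in sorted(tiers.items())}
    return report


def score_aggregates(forecasts, d: Dataset, method: str | None = None) -> ScoreReport:
    """Score a collection of :class:`AggregateForecast` against a dataset's key."""
    forecasts = list(forecasts)
    if not forecasts:
        raise ValidationError("empty forecast collection")
    label = method or forecasts[0].method
    fmap = {f.event_id: f.probability for f in forecasts}
    return transformed_brier(fmap, d.outcomes(), d.difficulties(), method=label)


def mean_individual_score(d: Dataset, extremised: bool = False,
                          a: float = 2.5) -> ScoreReport:
    """Benchmark: average the individual forecasters' scores within each
    event, then across events.

    When ``extremised``, the transform is applied to each individual
    forecast before scoring (individuals are recalibrated one by one; there
    is no aggregate to transform). Averaging within events first keeps the
    per-event pairing needed for paired bootstrap comparisons, since
    different forecasters answer different subsets of the questions.
    """
    outcomes = d.outcomes()
    groups = dict(iter(d.records.groupby("event_id", sort=True)))
    scores = {}
    for event_id in d.event_ids():
        rows = groups.get(event_id)
        if rows is None or len(rows) == 0:
            warnings.warn(f"event {event_id} has no retained forecasters; skipped")
            continue
        probs = rows["prob"].to_numpy(dtype=float)
        if extremised:
            probs = extremise(probs, a)
        out = outcomes[event_id]
        scores[event_id] = float(np.mean(100.0 - 100.0 * (out - probs) ** 2))
    if not scores:
        raise ValidationError("no scorable events")
    label = "individual_ext" if extremised else "individual_std"
    report = ScoreReport(method=label, per_event_scores=scores)
    diffs = d.difficulties()
    tiers = {}
    for ev, s in scores.items():
        tiers.setdefault(int(diffs[ev]), []).append(s)
    report.by_difficulty = {t: float(np.mean(v)) for t, v in sorted(tiers.items())}
    return report


def paired_differences(report_a: ScoreReport, report_b: ScoreReport):
    """Per-event score differences a - b, ordered by sorted event_id.

    Returns (event_ids, diffs). The mean of the differences equals the
    difference of mean scores. Both reports must cover the same events.
    """
    ev_a, ev_b = set(report_a.per_event_scores), set(report_b.per_event_scores)
    if ev_a != ev_b:
        raise ValidationError(
            f"event sets differ: only in a {sorted(ev_a - ev_b)[:5]}, "
            f"only in b {sorted(ev_b - ev_a)[:5]}"
        )
    event_ids = sorted(ev_a)
    diffs = np.array(
        [report_a.per_event_scores[e] - report_b.per_event_scores[e]
         for e in event_ids]
    )
    return event_ids, diffs
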