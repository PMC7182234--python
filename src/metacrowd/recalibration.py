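"""Leave-one-out cross-validated selection of the extremisation strength.

For each held-out event k, the recalibration parameter a_k is the grid value
maximizing the mean transformed Brier score of the extremised standard
aggregates over all *other* events; the held-out event is then forecast with
extremise(aggregate_k, a_k). The grid runs from 0 to 10 in steps of 0.01
(1001 points); ties are broken toward the smallest a, the least aggressive
transform. The held-out outcome never influences a_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregation import AggregateForecast, aggregate_dataset, extremise
from .data import Dataset
from .errors import ValidationError

DEFAULT_GRID = np.round(np.linspace(0.0, 10.0, 1001), 2)


@dataclass
class RecalibrationTrace:
    """Audit trail of the per-event parameters selected by LOO."""

    method: str
    per_event_a: dict[str, float]
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    objective: dict[str, float] = field(default_factory=dict)  # training score at a_k


def _score_matrix(probs: np.ndarray, outcomes: np.ndarray,
                  grid: np.ndarray) -> np.ndarray:
    """scores[k, j] = transformed Brier of extremise(probs[k], grid[j])
    against outcomes[k]. probs may be 2-d (event x forecaster): the score is
    then the within-event mean over forecasters (individual benchmark)."""
    out = np.empty((probs.shape[0], len(grid)))
    for j, a in enumerate(grid):
        t = extremise(probs, a)
        if t.ndim == 1:
            out[:, j] = 100.0 - 100.0 * (outcomes - t) ** 2
        else:
            sq = (outcomes[:, None] - t) ** 2
            out[:, j] = np.nanmean(100.0 - 100.0 * sq, axis=1)
    return out


def grid_search_a(forecasts, outcomes, grid=DEFAULT_GRID):
    """Grid value of a maximizing the mean transformed Brier score of the
    extremised forecasts; returns (a, score). Smallest a wins ties."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("empty recalibration grid")
    events = sorted(forecasts)
    if not events:
        raise ValidationError("need at least one event")
    missing = set(events) - set(outcomes)
    if missing:
        raise ValidationError(f"no outcome for events {sorted(missing)[:5]}")
    p = np.array([forecasts[e] for e in events], dtype=float)
    o = np.array([outcomes[e] for e in events], dtype=float)
    scores = _score_matrix(p, o, grid).mean(axis=0)
    j = int(np.argmax(scores))  # first max = smallest a on ties
    return float(grid[j]), float(scores[j])


def _event_probs(d: Dataset, method: str):
    """(event_ids, probs) where probs is 1-d standard aggregates, or a 2-d
    NaN-padded (event x forecaster) matrix for the individual benchmark."""
    if method == "individual":
        groups = dict(iter(d.records.groupby("event_id", sort=True)))
        ids = [e for e in d.event_ids() if e in groups]
        cols = max(len(groups[e]) for e in ids)
        mat = np.full((len(ids), cols), np.nan)
        for i, ev in enumerate(ids):
            vals = groups[ev]["prob"].to_numpy(dtype=float)
            mat[i, : len(vals)] = vals
        return ids, mat
    forecasts = aggregate_dataset(d, method, a=None)
    return [f.event_id for f in forecasts], np.array(
        [f.probability for f in forecasts]
    )


def loo_recalibrate(d: Dataset, method: str, grid=DEFAULT_GRID):
    """LOO-recalibrated forecasts for one method on a filtered dataset.

    ``method`` is a base aggregator ("simple", "mpw", "pivot") or
    "individual". Returns (forecasts, trace): one extremised
    :class:`AggregateForecast` per event (for "individual", the probability
    reported is the within-event mean of the individually extremised
    forecasts, matching how that benchmark is scored) and the trace of
    selected a values.
    """
    grid = np.asarray(grid, dtype=float)
    event_ids, probs = _event_probs(d, method)
    if len(event_ids) < 2:
        raise ValidationError("leave-one-out needs at least two events")
    outcomes = d.outcomes()
    o = np.array([outcomes[e] for e in event_ids], dtype=float)

    scores = _score_matrix(probs, o, grid)  # K x G
    total = scores.sum(axis=0)
    K = len(event_ids)
    counts = d.records["event_id"].value_counts()

    forecasts, per_event_a, objective = [], {}, {}
    for k, ev in enumerate(event_ids):
        train = (total - scores[k]) / (K - 1)
        j = int(np.argmax(train))
        a_k = float(grid[j])
        per_event_a[ev] = a_k
        objective[ev] = float(train[j])
        if method == "individual":
            row = probs[k][~np.isnan(probs[k])]
            prob_k = float(np.mean(extremise(row, a_k)))
            n_k = len(row)
        else:
            prob_k = float(extremise(probs[k], a_k))
            n_k = int(counts.get(ev, 0)) or 1
        forecasts.append(
            AggregateForecast(event_id=ev, method=f"{method}_loo",
                              probability=prob_k, n_forecasters=n_k,
                              recalibration_a=a_k)
        )
    trace = RecalibrationTrace(method=method, per_event_a=per_event_a,
                               grid=grid, objective=objective)
    return forecasts, trace


def loo_score_report(d: Dataset, method: str, grid=DEFAULT_GRID):
    """ScoreReport for the LOO-recalibrated method (helper for comparisons)."""
    from .scoring import ScoreReport, transformed_brier  # local to avoid cycle

    forecasts, trace = loo_recalibrate(d, method, grid=grid)
    if method == "individual":
        # score each forecaster individually under a_k, then average in-event
        outcomes = d.outcomes()
        scores = {}
        for f in forecasts:
            probs = d.records_for(f.event_id)["prob"].to_numpy(dtype=float)
            t = extremise(probs, f.recalibration_a)
            scores[f.event_id] = float(
                np.mean(100.0 - 100.0 * (outcomes[f.event_id] - t) ** 2)
            )
        report = ScoreReport(method="individual_loo", per_event_scores=scores)
    else:
        fmap = {f.event_id: f.probability for f in forecasts}
        report = transformed_brier(fmap, d.outcomes(), d.difficulties(),
                                   method=f"{method}_loo")
    return report, trace
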