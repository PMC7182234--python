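"""Crowd aggregators and the extremisation transform.

The meta-probability-weighting (MPW) aggregate of an event is

    T_MPW = sum_i W_i * P_i,     W_i = |P_i - M_i| / sum_j |P_j - M_j|,

where P_i is forecaster i's probability that the statement is true and M_i
is their meta-prediction of the average probability reported by others. A
forecaster whose forecast equals their meta-prediction carries no private
information beyond the common prior and receives zero weight; when *every*
gap is zero the weights degenerate and we fall back to uniform weights (the
simple average), flagging the event.

Benchmarks: the simple unweighted average, and minimal pivoting
T_MP = mean(P) + (mean(P) - mean(M)) = 2*mean(P) - mean(M), which corrects
the crowd mean for shared information and may leave [0, 1] (clamped here
before any scoring or extremisation).

Extremisation pushes an aggregate away from 1/2:

    t(p) = p^a / (p^a + (1-p)^a)

with a > 1 extremising, a = 1 the identity and 0 < a < 1 anti-extremising;
a = 0 is accepted (so recalibration grids may include it) and takes the
a -> 0+ limit: interior inputs collapse to 1/2, the endpoints stay fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import Dataset
from .errors import ValidationError

#: Fixed extremisation strength used in reproduction mode (chosen a priori
#: from the large-scale calibration literature, not fitted to any dataset).
DEFAULT_A = 2.5

BASE_METHODS = ("simple", "mpw", "pivot")


@dataclass(frozen=True)
class WeightVector:
    """Normalized per-forecaster MPW weights for one event."""

    weights: np.ndarray
    fallback_used: bool
    event_id: str | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if (w < 0).any():
            raise ValidationError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValidationError(f"weights sum to {w.sum()!r}, expected 1")


@dataclass(frozen=True)
class AggregateForecast:
    """A method's probability forecast for one event."""

    event_id: str
    method: str  # e.g. "mpw_ext", "simple_std"
    probability: float
    n_forecasters: int
    recalibration_a: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(
                f"aggregate probability {self.probability!r} outside [0, 1]"
            )
        if self.n_forecasters < 1:
            raise ValidationError("n_forecasters must be >= 1")


def _check_pair(probs, metas):
    p = np.asarray(probs, dtype=float)
    m = np.asarray(metas, dtype=float)
    if p.ndim != 1 or m.ndim != 1:
        raise ValidationError("probs and metas must be 1-d sequences")
    if len(p) != len(m):
        raise ValidationError(f"length mismatch: {len(p)} probs vs {len(m)} metas")
    if len(p) == 0:
        raise ValidationError("need at least one forecaster")
    for name, arr in (("probs", p), ("metas", m)):
        if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
            raise ValidationError(f"{name} contain values outside [0, 1]")
    return p, m


def mpw_weights(probs, metas, event_id: str | None = None) -> WeightVector:
    """Per-forecaster weights proportional to |P_i - M_i|, summing to one.

    Falls back to uniform weights (flagged) when every forecaster's gap is
    exactly zero.
    """
    p, m = _check_pair(probs, metas)
    gaps = np.abs(p - m)
    total = gaps.sum()
    if total == 0.0:
        return WeightVector(
            weights=np.full(len(p), 1.0 / len(p)),
            fallback_used=True,
            event_id=event_id,
        )
    return WeightVector(weights=gaps / total, fallback_used=False, event_id=event_id)


def mpw_aggregate(probs, metas) -> float:
    """Meta-probability-weighted aggregate: a convex combination of the
    individual forecasts, so it always lies within [min(P), max(P)]."""
    p, _ = _check_pair(probs, metas)
    w = mpw_weights(probs, metas)
    return float(np.dot(w.weights, p))


def simple_average(probs) -> float:
    """Arithmetic mean of the individual forecasts."""
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("need at least one forecast")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("probs contain values outside [0, 1]")
    return float(p.mean())


def minimal_pivot(probs, metas, clamp: bool = True) -> float:
    """Minimal-pivoting aggregate 2*mean(P) - mean(M).

    The pivot doubles the gap between the crowd mean and the mean
    meta-prediction; the raw value can leave [0, 1] and is clamped by
    default so downstream scoring and extremisation see a probability.
    """
    p, m = _check_pair(probs, metas)
    raw = 2.0 * p.mean() - m.mean()
    if clamp:
        return float(min(1.0, max(0.0, raw)))
    return float(raw)


def extremise(p, a):
    """Recalibration transform t(p) = p^a / (p^a + (1-p)^a).

    Accepts scalars or arrays. Fixed points t(0)=0, t(0.5)=0.5, t(1)=1 for
    every a > 0; the identity at a = 1; symmetric, t(1-p) = 1 - t(p). a = 0
    takes the a -> 0+ limit (interior inputs map to 0.5, endpoints stay
    fixed); a < 0 is rejected.
    """
    if a < 0:
        raise ValidationError(f"recalibration parameter a must be >= 0, got {a}")
    arr = np.asarray(p, dtype=float)
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValidationError("probabilities must lie in [0, 1]")
    if a == 0:
        # a -> 0+ limit: interior points collapse to 1/2, the endpoints are
        # fixed points for every a > 0 and stay fixed in the limit
        out = np.where(arr == 0.0, 0.0, np.where(arr == 1.0, 1.0, 0.5))
    else:
        num = arr ** a
        den = num + (1.0 - arr) ** a
        out = num / den
    if np.isscalar(p) or np.asarray(p).ndim == 0:
        return float(out)
    return out


def event_arrays(d: Dataset, event_id: str, require_meta: bool):
    """(probs, metas) for one event; records lacking a meta-prediction are
    dropped only when the aggregator needs them."""
    rows = d.records_for(event_id)
    if require_meta:
        rows = rows[~rows["meta_prob"].isna()]
    p = rows["prob"].to_numpy(dtype=float)
    m = rows["meta_prob"].to_numpy(dtype=float)
    return p, m


def aggregate_event(d: Dataset, event_id: str, base: str) -> tuple[float, int]:
    """Standard (un-extremised) aggregate for one event; returns (prob, n)."""
    if base not in BASE_METHODS:
        raise ValidationError(f"unknown method {base!r}; expected {BASE_METHODS}")
    require_meta = base in ("mpw", "pivot")
    p, m = event_arrays(d, event_id, require_meta)
    if len(p) == 0:
        raise ValidationError(f"event {event_id!r} has no usable records")
    if base == "simple":
        return simple_average(p), len(p)
    if base == "mpw":
        return mpw_aggregate(p, m), len(p)
    return minimal_pivot(p, m), len(p)


def aggregate_dataset(d: Dataset, method: str, a: float | None = None):
    """One :class:`AggregateForecast` per retained event.

    ``method`` is a base name from :data:`BASE_METHODS`; pass ``a`` to get
    the extremised variant (applied to the aggregate, after clamping in the
    minimal-pivot case). Events with no usable records are skipped with a
    warning.
    """
    if method not in BASE_METHODS:
        raise ValidationError(f"unknown method {method!r}; expected {BASE_METHODS}")
    require_meta = method in ("mpw", "pivot")
    out = []
    label = f"{method}_std" if a is None else f"{method}_ext"
    groups = dict(iter(d.records.groupby("event_id", sort=True)))
    for event_id in d.event_ids():
        rows = groups.get(event_id)
        if rows is not None and require_meta:
            rows = rows[~rows["meta_prob"].isna()]
        if rows is None or len(rows) == 0:
            warnings.warn(f"skipping event {event_id}: no usable records")
            continue
        p = rows["prob"].to_numpy(dtype=float)
        m = rows["meta_prob"].to_numpy(dtype=float)
        if method == "simple":
            prob = simple_average(p)
        elif method == "mpw":
            prob = mpw_aggregate(p, m)
        else:
            prob = minimal_pivot(p, m)
        n = len(p)
        if a is not None:
            prob = extremise(prob, a)
        out.append(
            AggregateForecast(
                event_id=event_id,
                method=label,
                probability=prob,
                n_forecasters=n,
                recalibration_a=a,
            )
        )
    return out
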