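"""Canonical in-memory containers for crowd-forecasting data, plus the
pre-analysis exclusion filters.

A study is a pair of tables:

* **responses** — one row per (forecaster, event): a binary vote on the
  statement, the predicted share of others voting true, a probability
  forecast ``prob`` (P_ik), a meta-prediction ``meta_prob`` (the forecaster's
  estimate of the average probability others will report, M_ik), and a
  self-reported-cheating flag.
* **events** — one row per event: the ground-truth outcome (1 = statement
  true) and a difficulty tier in 1..5.

Probabilities are always stored on the unit scale [0, 1]; scale conversion
happens at read time (see :mod:`metacrowd.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

RESPONSE_COLUMNS = [
    "forecaster_id",
    "event_id",
    "vote",
    "meta_vote_share",
    "prob",
    "meta_prob",
    "cheater",
]
EVENT_COLUMNS = ["event_id", "truth", "difficulty", "statement"]


@dataclass(frozen=True)
class ForecastRecord:
    """One forecaster's responses to one event."""

    forecaster_id: str
    event_id: str
    vote: bool
    meta_vote_share: float
    prob: float
    meta_prob: float
    cheater_flag: bool = False

    def __post_init__(self):
        for name in ("meta_vote_share", "prob", "meta_prob"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v!r} outside [0, 1]")


@dataclass(frozen=True)
class EventKey:
    """Event identity, binary ground truth and difficulty tier."""

    event_id: str
    truth: int
    difficulty: int
    statement_text: str = ""

    def __post_init__(self):
        if self.truth not in (0, 1):
            raise ValidationError(f"truth must be 0 or 1, got {self.truth!r}")
        if self.difficulty not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"difficulty must be in 1..5, got {self.difficulty!r}"
            )


@dataclass
class Dataset:
    """Responses + event key, with a provenance log of applied filters.

    ``records`` and ``events`` are pandas DataFrames with the canonical
    columns (:data:`RESPONSE_COLUMNS`, :data:`EVENT_COLUMNS`).
    """

    records: pd.DataFrame
    events: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.records = _canonical_records(self.records)
        self.events = _canonical_events(self.events)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_forecasters(self) -> int:
        return self.records["forecaster_id"].nunique()

    def event_ids(self) -> list[str]:
        return sorted(self.events["event_id"])

    def outcomes(self) -> dict[str, int]:
        return dict(zip(self.events["event_id"], self.events["truth"].astype(int)))

    def difficulties(self) -> dict[str, int]:
        return dict(
            zip(self.events["event_id"], self.events["difficulty"].astype(int))
        )

    def records_for(self, event_id: str) -> pd.DataFrame:
        return self.records[self.records["event_id"] == event_id]

    def iter_records(self):
        for row in self.records.itertuples(index=False):
            yield ForecastRecord(
                forecaster_id=row.forecaster_id,
                event_id=row.event_id,
                vote=bool(row.vote),
                meta_vote_share=float(row.meta_vote_share),
                prob=float(row.prob),
                meta_prob=float(row.meta_prob),
                cheater_flag=bool(row.cheater),
            )

    def validate(self) -> None:
        r = self.records
        dup = r.duplicated(subset=["forecaster_id", "event_id"])
        if dup.any():
            pairs = r.loc[dup, ["forecaster_id", "event_id"]].head(5)
            raise ValidationError(
                f"duplicate (forecaster, event) pairs, e.g.\n{pairs}"
            )
        for col in ("prob", "meta_vote_share"):
            vals = r[col].to_numpy(dtype=float)
            bad = ~np.isnan(vals) & ((vals < 0) | (vals > 1))
            if bad.any():
                raise ValidationError(
                    f"{col} outside [0, 1] in {int(bad.sum())} records"
                )
        meta = r["meta_prob"].to_numpy(dtype=float)
        bad = ~np.isnan(meta) & ((meta < 0) | (meta > 1))
        if bad.any():
            raise ValidationError(
                f"meta_prob outside [0, 1] in {int(bad.sum())} records"
            )
        known = set(self.events["event_id"])
        missing = set(r["event_id"]) - known
        if missing:
            raise ValidationError(
                f"{len(missing)} event ids in responses lack an event-key row, "
                f"e.g. {sorted(missing)[:5]}"
            )

    def log(self, message: str) -> "Dataset":
        return replace(self, provenance=self.provenance + [message])

    def subset_events(self, event_ids) -> "Dataset":
        """Restrict to the given events (used for per-difficulty analyses)."""
        keep = set(event_ids)
        return Dataset(
            records=self.records[self.records["event_id"].isin(keep)],
            events=self.events[self.events["event_id"].isin(keep)],
            provenance=self.provenance + [f"subset to {len(keep)} events"],
        )


def _canonical_records(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in RESPONSE_COLUMNS:
        if col not in df.columns:
            if col == "meta_prob":
                df[col] = np.nan
            elif col == "cheater":
                df[col] = False
            else:
                raise ValidationError(f"records table missing column {col!r}")
    df = df[RESPONSE_COLUMNS]
    df["forecaster_id"] = df["forecaster_id"].astype(str)
    df["event_id"] = df["event_id"].astype(str)
    df["vote"] = df["vote"].astype(bool)
    df["cheater"] = df["cheater"].astype(bool)
    for col in ("meta_vote_share", "prob", "meta_prob"):
        df[col] = df[col].astype(float)
    return df.reset_index(drop=True)


def _canonical_events(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "statement" not in df.columns:
        df["statement"] = ""
    for col in ("event_id", "truth", "difficulty"):
        if col not in df.columns:
            raise ValidationError(f"events table missing column {col!r}")
    df = df[EVENT_COLUMNS]
    df["event_id"] = df["event_id"].astype(str)
    df["truth"] = df["truth"].astype(int)
    df["difficulty"] = df["difficulty"].astype(int)
    if df["event_id"].duplicated().any():
        raise ValidationError("duplicate event_id in event-key table")
    if not df["truth"].isin([0, 1]).all():
        raise ValidationError("truth must be 0 or 1")
    if not df["difficulty"].isin([1, 2, 3, 4, 5]).all():
        raise ValidationError("difficulty must be an integer tier in 1..5")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Exclusion filters
# ---------------------------------------------------------------------------

def exclude_cheaters(d: Dataset) -> Dataset:
    """Drop every record from forecasters who self-reported cheating.

    Removal is per forecaster: all of a flagged forecaster's responses go.
    Idempotent and commutes with :func:`exclude_inconsistent`.
    """
    flagged = d.records.loc[d.records["cheater"], "forecaster_id"].unique()
    kept = d.records[~d.records["forecaster_id"].isin(flagged)]
    if len(kept) == 0 and len(d.records) > 0:
        warnings.warn("all forecasters were flagged as cheaters; dataset is empty")
    out = Dataset(records=kept, events=d.events, provenance=list(d.provenance))
    return out.log(
        f"exclude_cheaters: removed {len(flagged)} forecasters "
        f"({len(d.records) - len(kept)} records)"
    )


def exclude_inconsistent(d: Dataset) -> Dataset:
    """Drop (forecaster, event) pairs whose vote contradicts their forecast.

    A record is inconsistent when the forecaster voted true but reported a
    probability strictly below 0.5, or voted false with a probability
    strictly above 0.5. Probability exactly 0.5 is consistent with either
    vote (the rule uses strict inequalities). Removal is per pair — the
    forecaster's other responses are untouched.
    """
    r = d.records
    bad = (r["vote"] & (r["prob"] < 0.5)) | (~r["vote"] & (r["prob"] > 0.5))
    kept = r[~bad]
    out = Dataset(records=kept, events=d.events, provenance=list(d.provenance))
    return out.log(
        f"exclude_inconsistent: removed {int(bad.sum())} (forecaster, event) pairs"
    )


def apply_standard_filters(d: Dataset) -> Dataset:
    """Cheater exclusion followed by vote-probability consistency (they commute)."""
    return exclude_inconsistent(exclude_cheaters(d))
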