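"""Readers and writers for response tables, event keys and aggregate files.

All on-disk formats are delimited text (CSV/TSV) with a header row. Column
names and the probability scale of the response file vary between survey
exports, so the reader takes a :class:`ResponseDialect` describing the
mapping; a dialect can be loaded from a YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import Dataset
from .errors import ConfigError, RowError, ValidationError

_TRUE_TOKENS = {"true", "t", "yes", "y", "1", "1.0"}
_FALSE_TOKENS = {"false", "f", "no", "n", "0", "0.0"}


@dataclass(frozen=True)
class ResponseDialect:
    """Column mapping and scale declaration for a response file.

    ``scale`` is ``"percent"`` (0–100 on disk) or ``"unit"`` (0–1). Votes and
    cheater flags may be encoded as text ("true"/"false"), integers or
    booleans; all are absorbed.
    """

    scale: str = "unit"
    delimiter: str = ","
    columns: dict = field(
        default_factory=lambda: {
            "forecaster_id": "forecaster_id",
            "event_id": "event_id",
            "vote": "vote",
            "meta_vote_share": "meta_vote_share",
            "prob": "prob",
            "meta_prob": "meta_prob",
            "cheater": "cheater",
        }
    )

    def __post_init__(self):
        if self.scale not in ("percent", "unit"):
            raise ConfigError(f"scale must be 'percent' or 'unit', got {self.scale!r}")

    @classmethod
    def from_yaml(cls, path) -> "ResponseDialect":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "scale" in raw:
            kwargs["scale"] = raw["scale"]
        if "delimiter" in raw:
            kwargs["delimiter"] = raw["delimiter"]
        if "columns" in raw:
            base = cls().columns | dict(raw["columns"])
            kwargs["columns"] = base
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _parse_bool(value, line: int, colname: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise RowError(f"cannot parse {colname} value {value!r} as boolean", line)


def _parse_prob(value, line: int, colname: str, scale: str) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)) or (
        isinstance(value, str) and value.strip() == ""
    ):
        return float("nan")
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise RowError(f"cannot parse {colname} value {value!r} as a number", line)
    if scale == "percent":
        x = x / 100.0
    if not 0.0 <= x <= 1.0:
        raise RowError(
            f"{colname} value {value!r} outside the declared {scale} scale", line
        )
    return x


def read_responses(path, dialect: ResponseDialect | None = None,
                   events: pd.DataFrame | None = None) -> Dataset:
    """Read a response table into a :class:`Dataset`.

    If ``events`` is None, a skeletal event-key table is synthesized from the
    event ids present (truth/difficulty must then be attached later via
    :func:`read_events` + :func:`attach_events`).
    """
    dialect = dialect or ResponseDialect()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"response file not found: {path}")
    try:
        raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str,
                          keep_default_na=False)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame()
    if raw.empty:
        empty = pd.DataFrame({
            "forecaster_id": pd.Series(dtype=str),
            "event_id": pd.Series(dtype=str),
            "vote": pd.Series(dtype=bool),
            "meta_vote_share": pd.Series(dtype=float),
            "prob": pd.Series(dtype=float),
            "meta_prob": pd.Series(dtype=float),
            "cheater": pd.Series(dtype=bool),
        })
        ev = events if events is not None else pd.DataFrame({
            "event_id": pd.Series(dtype=str),
            "truth": pd.Series(dtype=int),
            "difficulty": pd.Series(dtype=int),
        })
        ds = Dataset(records=empty, events=ev)
        return ds.log(f"read {path.name}: 0 records")

    colmap = dialect.columns
    optional = {"meta_prob", "cheater"}
    for canonical, source in colmap.items():
        if source not in raw.columns:
            if canonical in optional:
                continue
            raise ConfigError(
                f"response file {path.name} lacks column {source!r} "
                f"(mapped to {canonical!r}); available: {list(raw.columns)}"
            )

    n = len(raw)
    out = {}
    out["forecaster_id"] = raw[colmap["forecaster_id"]].astype(str)
    out["event_id"] = raw[colmap["event_id"]].astype(str)
    # header is line 1, first data row line 2
    lines = range(2, n + 2)
    out["vote"] = [
        _parse_bool(v, ln, "vote")
        for v, ln in zip(raw[colmap["vote"]], lines)
    ]
    out["meta_vote_share"] = [
        _parse_prob(v, ln, "meta_vote_share", dialect.scale)
        for v, ln in zip(raw[colmap["meta_vote_share"]], lines)
    ]
    out["prob"] = [
        _parse_prob(v, ln, "prob", dialect.scale)
        for v, ln in zip(raw[colmap["prob"]], lines)
    ]
    if colmap["meta_prob"] in raw.columns:
        out["meta_prob"] = [
            _parse_prob(v, ln, "meta_prob", dialect.scale)
            for v, ln in zip(raw[colmap["meta_prob"]], lines)
        ]
    else:
        out["meta_prob"] = [float("nan")] * n
    if colmap["cheater"] in raw.columns:
        out["cheater"] = [
            _parse_bool(v, ln, "cheater")
            for v, ln in zip(raw[colmap["cheater"]], lines)
        ]
    else:
        out["cheater"] = [False] * n

    records = pd.DataFrame(out)
    if events is None:
        events = pd.DataFrame({
            "event_id": sorted(records["event_id"].unique()),
            "truth": 0,
            "difficulty": 1,
        })
        prov = [f"read {path.name}: {n} records ({dialect.scale} scale -> unit); "
                "event key synthesized (truth/difficulty placeholders)"]
    else:
        prov = [f"read {path.name}: {n} records ({dialect.scale} scale -> unit)"]
    return Dataset(records=records, events=events, provenance=prov)


def read_events(path) -> pd.DataFrame:
    """Read an event-key CSV with columns event_id, truth, difficulty[, statement]."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"event-key file not found: {path}")
    df = pd.read_csv(path)
    for col in ("event_id", "truth", "difficulty"):
        if col not in df.columns:
            raise ConfigError(f"event-key file lacks column {col!r}")
    return df


def attach_events(d: Dataset, events: pd.DataFrame) -> Dataset:
    """Replace the event-key table of a dataset (validates referential integrity)."""
    return Dataset(records=d.records, events=events,
                   provenance=d.provenance + ["event key attached"])


def write_aggregates(forecasts, path) -> None:
    """Write aggregate forecasts to CSV, one row per (event, method).

    Probabilities are written at full precision (repr round-trip), so
    ``read_aggregates(write_aggregates(x)) == x`` to better than 1e-12.
    """
    forecasts = list(forecasts)
    if not forecasts:
        raise ValidationError("cannot write an empty aggregate collection")
    df = pd.DataFrame(
        {
            "event_id": [f.event_id for f in forecasts],
            "method": [f.method for f in forecasts],
            "probability": [f.probability for f in forecasts],
            "n_forecasters": [f.n_forecasters for f in forecasts],
            "recalibration_a": [
                "" if f.recalibration_a is None else f.recalibration_a
                for f in forecasts
            ],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_aggregates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("event_id", "method", "probability"):
        if col not in df.columns:
            raise ConfigError(f"aggregate file lacks column {col!r}")
    df["event_id"] = df["event_id"].astype(str)
    return df
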