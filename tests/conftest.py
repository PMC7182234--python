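import hypothesis
import numpy as np
import pandas as pd
import pytest

from metacrowd.data import Dataset

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


def make_dataset(records, events, provenance=None):
    """Build a Dataset from lists of dicts (test convenience)."""
    return Dataset(
        records=pd.DataFrame(records),
        events=pd.DataFrame(events),
        provenance=provenance or [],
    )


def record(forecaster, event, prob, meta=None, vote=None, share=0.5,
           cheater=False):
    if vote is None:
        vote = prob >= 0.5
    return {
        "forecaster_id": forecaster, "event_id": event, "vote": vote,
        "meta_vote_share": share, "prob": prob,
        "meta_prob": np.nan if meta is None else meta, "cheater": cheater,
    }


def event(event_id, truth, difficulty=1):
    return {"event_id": event_id, "truth": truth, "difficulty": difficulty,
            "statement": ""}


@pytest.fixture
def two_event_dataset():
    """Two events, three forecasters each, no filtering issues."""
    records = [
        record("f1", "e1", 0.9, 0.5), record("f2", "e1", 0.6, 0.6),
        record("f3", "e1", 0.7, 0.4),
        record("f1", "e2", 0.2, 0.5), record("f2", "e2", 0.4, 0.4),
        record("f3", "e2", 0.3, 0.6),
    ]
    events = [event("e1", 1, 1), event("e2", 0, 2)]
    return make_dataset(records, events)


@pytest.fixture
def dirty_dataset():
    """Contains a self-reported cheater and an inconsistent vote."""
    records = [
        record("f1", "e1", 0.9, 0.5),
        record("f2", "e1", 0.3, 0.6, vote=True),    # inconsistent: true @ 0.3
        record("f3", "e1", 0.5, 0.5, vote=False),   # boundary: consistent
        record("f4", "e1", 0.8, 0.7, cheater=True),
        record("f4", "e2", 0.6, 0.5, cheater=True),
        record("f1", "e2", 0.2, 0.5, vote=False),
        record("f2", "e2", 0.8, 0.3, vote=False),   # inconsistent: false @ 0.8
    ]
    events = [event("e1", 1, 1), event("e2", 0, 1)]
    return make_dataset(records, events)
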