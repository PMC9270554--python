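import numpy as np
import pandas as pd
import pytest

from hypoflow import EventTable, FlowSimConfig, GateSet

# gates that separate the default synthetic populations cleanly
DEFAULT_GATES = GateSet(nao_threshold=700, tmre_threshold=500, pi_threshold=400)


@pytest.fixture
def gates() -> GateSet:
    return DEFAULT_GATES


@pytest.fixture
def flow_config() -> FlowSimConfig:
    return FlowSimConfig()


def make_events(fl1, fl2, fl3, **meta) -> EventTable:
    """Event table with explicit fluorescence values and unit scatter."""
    n = len(fl1)
    return EventTable(
        data=pd.DataFrame(
            {
                "FSC": np.full(n, 1000.0),
                "SSC": np.full(n, 500.0),
                "FL1": np.asarray(fl1, float),
                "FL2": np.asarray(fl2, float),
                "FL3": np.asarray(fl3, float),
            }
        ),
        **meta,
    )


def brute_force_es(scores, member, weight=1.0):
    """Independent O(n) running-sum oracle for the enrichment score.

    Walks the ranked list position by position; the ES is the running-sum
    value of largest magnitude (positive preferred on exact magnitude ties).
    """
    scores = np.asarray(scores, float)
    member = np.asarray(member, bool)
    n = len(scores)
    n_hits = member.sum()
    w = np.abs(scores) ** weight
    total = w[member].sum()
    if total == 0:
        w = np.ones(n)
        total = float(n_hits)
    run = 0.0
    values = []
    for i in range(n):
        run += w[i] / total if member[i] else -1.0 / (n - n_hits)
        values.append(run)
    mx, mn = max(values), min(values)
    # same tie convention as the implementation: positive wins near-ties
    return mx if mx >= -mn - 1e-12 else mn
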