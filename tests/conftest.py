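"""Shared fixtures: archetypes and an expensive trained-classifier setup.

The trained benchmark (monoculture study -> Stage-1 clustering -> Stage-2
forest) is session-scoped because several test modules and the acceptance
suite evaluate against the same trained model.
"""

import numpy as np
import pandas as pd
import pytest

from flowdeconv import benchmark as bm
from flowdeconv.events import CHANNELS, EventTable, SampleMeta
from flowdeconv.synthetic import GroundTruth, make_archetypes, simulate_sample


@pytest.fixture(scope="session")
def archetypes():
    return make_archetypes()


@pytest.fixture(scope="session")
def trained_benchmark():
    """Monoculture-trained classifier at the default (overlapping) geometry."""
    return bm.train_benchmark_classifier(seed=1)


@pytest.fixture()
def co_meta():
    return SampleMeta("co-test", "co", "glucose", "simple")


@pytest.fixture()
def mono_meta():
    return SampleMeta("mono-test", "mono:Bv", "glucose", "simple")


@pytest.fixture()
def small_coculture(archetypes, co_meta):
    """A moderately sized four-species co-culture with debris."""
    truth = GroundTruth("co-test", (0.4, 0.3, 0.2, 0.1), 1.2e7, 0.1)
    return simulate_sample(co_meta, archetypes, truth, seed=42, max_events=8000)


def make_table(mat, sample_id="t", extra=None):
    """Build an EventTable from a raw (n, 5) array."""
    df = pd.DataFrame(np.asarray(mat, dtype=float), columns=list(CHANNELS))
    if extra:
        for k, v in extra.items():
            df[k] = v
    return EventTable(df, sample_id=sample_id)
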