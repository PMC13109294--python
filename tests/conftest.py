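import numpy as np
import pandas as pd
import pytest

from omicboost import OmicsBlock, OutcomeVector, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_block(values, name="block", feature_ids=None, sample_ids=None,
               feature_axis=None):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    return OmicsBlock(
        name,
        feature_ids or [f"f{i}" for i in range(p)],
        sample_ids or [f"S{j}" for j in range(n)],
        values, feature_axis)


def make_metadata(sample_ids, **factors):
    return SampleMetadata(pd.DataFrame(factors, index=list(sample_ids)))


def make_outcome(sample_ids, y, task="regression"):
    return OutcomeVector(list(sample_ids), np.asarray(y, float), task)


@pytest.fixture
def small_block():
    return make_block([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
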