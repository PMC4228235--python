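import numpy as np
import pandas as pd
import pytest

from devchar import ExpressionMatrix, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(20130947)


def make_matrix(values, feature_ids=None, sample_ids=None, feature_level="gene"):
    values = np.asarray(values, float)
    n, m = values.shape
    feature_ids = feature_ids or [f"g{i}" for i in range(n)]
    sample_ids = sample_ids or [f"s{j}" for j in range(m)]
    data = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                        columns=sample_ids)
    return ExpressionMatrix(data, feature_level=feature_level)


def make_duplicate_meta(sample_ids, ages):
    """Metadata for two replicate series laid out as [rep1 ages..., rep2 ages...]."""
    half = len(sample_ids) // 2
    rows = []
    for k, sid in enumerate(sample_ids):
        rep = "r1" if k < half else "r2"
        rows.append((sid, ages[k], rep, "", ""))
    return SampleMetadata(pd.DataFrame(
        rows, columns=["sample_id", "age_days", "replicate_id", "group", "pair_id"]))


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture
def duplicate_meta_factory():
    return make_duplicate_meta
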