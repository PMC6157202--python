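import numpy as np
import pytest

from msld_sampen import (
    FeatureTable,
    FeatureVector,
    SampEnParams,
    extract_feature_table,
    gen_labeled_set,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_synth_set():
    """Small but full-length synthetic set (5 records/class, 1024 samples)."""
    return gen_labeled_set(n_per_class=5, n_samples=1024, seed=7)


@pytest.fixture(scope="session")
def small_feature_table(small_synth_set):
    return extract_feature_table(
        small_synth_set, 1, 10, SampEnParams(m=2, r=0.25)
    )


def make_table(X, labels, d_min=1, params=None):
    """Build a FeatureTable directly from a matrix (classification tests)."""
    X = np.asarray(X, dtype=float)
    d_max = d_min + X.shape[1] - 1
    rows = [
        FeatureVector(
            record_id=f"rec-{i:04d}",
            label=str(lab),
            values=X[i],
            d_min=d_min,
            d_max=d_max,
            params=params,
        )
        for i, lab in enumerate(labels)
    ]
    return FeatureTable(rows)


@pytest.fixture(scope="session")
def pipeline_table_seed1():
    """Study-scale pipeline features: 100 records/class, 4096 samples,
    d = 1..20, m = 2, r = 0.25, master seed 1. Shared by the heavier
    end-to-end checks so the extraction cost is paid once."""
    signal_set = gen_labeled_set(n_per_class=100, n_samples=4096, seed=1)
    return extract_feature_table(signal_set, 1, 20, SampEnParams(m=2, r=0.25))
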