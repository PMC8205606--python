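import numpy as np
import pytest

import nirleaf as nl


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bench():
    """Compact well-separated benchmark: 8 leaves per maturity level."""
    return nl.easy_benchmark(seed=7, n_per_class=8)


@pytest.fixture(scope="session")
def small_bench_matrices(small_bench):
    """Preprocessed train/test split of the compact benchmark."""
    pipe = nl.default_pipeline(step_nm=small_bench.grid.step_nm)
    X = pipe.fit_transform(small_bench.mean_spectra())
    y = small_bench.labels()
    split = nl.split_dataset(X, 0.7)
    return (X[split.train_indices], y[split.train_indices],
            X[split.test_indices], y[split.test_indices])
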