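import numpy as np
import pytest

import contranet as cn


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """Small but structurally faithful cohort for fast end-to-end tests."""
    return cn.CohortConfig(
        n_per_group=6,
        n_rois=12,
        n_timepoints=120,
        module_sizes=(4, 4, 4),
        seed=1234,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_config):
    return cn.simulate_cohort(tiny_cohort_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_weighted_graph(rng, n, density=0.5):
    """Random symmetric nonnegative weighted graph used by oracle tests."""
    w = rng.random((n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(w * mask, k=1)
    w = w + w.T
    return cn.WeightedGraph(w, [f"N{i}" for i in range(n)])
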