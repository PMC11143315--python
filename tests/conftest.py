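import numpy as np
import pytest

import trisimnet as tsn


@pytest.fixture(scope="session")
def separable_cohort():
    """Well-separated 4-class cohort: downstream classifiers should ace it."""
    raw, truth = tsn.generate_cohort(
        tsn.CohortSpec(n=400, separation=6.0, noise_sd=1.0, seed=11)
    )
    return raw, truth


@pytest.fixture(scope="session")
def prepared(separable_cohort):
    raw, _ = separable_cohort
    return tsn.preprocess(raw)


@pytest.fixture(scope="session")
def small_graph(prepared):
    return tsn.build_graph(prepared, tsn.MetricSpec("cosine", 0.95))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
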