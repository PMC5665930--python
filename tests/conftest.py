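import numpy as np
import pandas as pd
import pytest

from metabotyper.synthetic import (
    CohortSpec,
    FeatureTableSpec,
    simulate_feature_table,
    simulate_turnover,
)

GROUP_LABELS_16_4 = (0,) * 16 + (1,) * 4


@pytest.fixture
def cohort_spec():
    return CohortSpec(seed=11)


@pytest.fixture
def noiseless_cohort():
    spec = CohortSpec(noise_cv=0.0, seed=5)
    table, truth = simulate_turnover(spec)
    return spec, table, truth


@pytest.fixture
def planted_feature_table():
    spec = FeatureTableSpec(
        n_features=120,
        group_labels=GROUP_LABELS_16_4,
        baseline_log_sd=0.25,
        planted=tuple((i, 4.0) for i in range(10)),
        seed=42,
    )
    table, truth = simulate_feature_table(spec)
    labels = pd.Series(truth["labels"])
    return table, labels, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
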