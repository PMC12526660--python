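import numpy as np
import pytest

from hrvpipe.labeling import build_reference_table
from hrvpipe.pipeline import cohort_features
from hrvpipe.synthetic import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def refs():
    """Printed-defaults reference table, fitted."""
    return build_reference_table()


@pytest.fixture(scope="session")
def small_cohort():
    """40 noise-free-ish records, 20 s each — cheap detector/feature input."""
    config = SyntheticCohortConfig(n_records=40, duration_s=20.0, seed=11)
    records, truths = generate_cohort(config)
    return config, records, truths


@pytest.fixture(scope="session")
def labeled_table(refs):
    """A medium synthetic feature table with targets, for model tests."""
    from hrvpipe.labeling import label_table

    config = SyntheticCohortConfig(n_records=600, duration_s=30.0, seed=5)
    features = cohort_features(config)
    labeled, _ = label_table(features, refs)
    return labeled


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
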