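import numpy as np
import pytest

from emgstress import experiment, io, synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """Ten synthetic subjects under the default stress model."""
    return synthetic.generate_cohort(n_subjects=10, seed=123)


@pytest.fixture(scope="session")
def feature_table_5min(default_cohort):
    return experiment.feature_table_for_length(default_cohort, 5.0)


@pytest.fixture()
def rest_segment():
    rng = np.random.default_rng(7)
    return io.Segment(
        subject_id="s1", scenario="rest", samples=rng.normal(0, 2, 930), fs=io.DEFAULT_FS
    )


def make_segment(samples, scenario="rest", subject_id="s1", fs=io.DEFAULT_FS):
    return io.Segment(
        subject_id=subject_id, scenario=scenario, samples=np.asarray(samples, float), fs=fs
    )
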