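import numpy as np
import pytest

from famseg.synthetic_data import study_cohort_config, simulate_dataset


@pytest.fixture(scope="session")
def study_cohort():
    """The default study-shaped synthetic cohort, shared across tests."""
    return simulate_dataset(study_cohort_config(seed=11))


@pytest.fixture(scope="session")
def cohort_files(study_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    return study_cohort.write(outdir)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
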