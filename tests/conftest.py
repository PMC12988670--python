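import numpy as np
import pytest

from vfarch import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient, 3-template cohort with sigma = 1 dB noise."""
    return synthetic.simulate_cohort(60, k_true=3, noise_sigma=1.0, seed=11)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    paths = small_cohort.write(d)
    return paths


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
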