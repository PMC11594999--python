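import numpy as np
import pytest

from flimtex.io import extract_roi
from flimtex.pipeline import feature_table
from flimtex.synthetic import generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort shared by pipeline-level tests: 4+4 patients."""
    return generate_cohort(
        n_per_group={"control": 4, "scd": 4},
        cells_per_patient={"control": 4, "nonsickled": 4, "sickled": 2},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return feature_table(small_cohort.cells)


@pytest.fixture
def roi_of():
    def _roi(matrix, record):
        return extract_roi(matrix, record.roi)

    return _roi
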