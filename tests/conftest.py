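import numpy as np
import pytest

from fcbiomarker import scca, synthetic


@pytest.fixture(scope="session")
def small_planted_cohort():
    """Small planted cohort shared by selection/pipeline tests."""
    attrs, fc, truth = synthetic.planted_cohort(
        n_subjects=120, n_fc=120, n_diagnosis_fc=5, n_site_fc=10, seed=42
    )
    return attrs, fc, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def attribute_matrix(attrs):
    return attrs[list(scca.ATTRIBUTE_COLUMNS)].to_numpy(dtype=float)
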