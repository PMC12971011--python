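import numpy as np
import pytest

from dwiaspects.atlas import build_synthetic_atlas


@pytest.fixture(scope="session")
def atlas64():
    """Reference synthetic atlas: 64^3 at 1 mm isotropic."""
    return build_synthetic_atlas((64, 64, 64), seed=7)


@pytest.fixture(scope="session")
def atlas40():
    """Small atlas for brute-force oracle comparisons."""
    return build_synthetic_atlas((40, 40, 40), seed=7)


@pytest.fixture(scope="session")
def atlas_cohort():
    """Cohort-scale atlas: 64^3 at 2 mm.

    Brain ~0.7 L with cortical territories of ~40-90 mL and nuclear
    regions of ~6 mL, so clinically sized lesions (4-200 mL) interact
    with the 1/3 rule the way patient lesions do.
    """
    return build_synthetic_atlas((64, 64, 64), spacing=(2.0, 2.0, 2.0), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
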