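import warnings

import numpy as np
import pytest

from twinstable import synthetic_data as sd

warnings.filterwarnings("ignore", category=RuntimeWarning, module="scipy")


@pytest.fixture(scope="session")
def default_cohort():
    return sd.generate_cohort(sd.CohortDesign(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    return sd.generate_cohort(sd.CohortDesign(n_mz_pairs=16, n_dz_pairs=8, seed=2))


@pytest.fixture
def cs_generator():
    """Compound-symmetric ACE generator: A=0.3, C=0.2, E=0.5 per visit."""
    return sd.ACEGenerator(
        sd.compound_symmetric_paths(0.3, 0.95, 3),
        sd.compound_symmetric_paths(0.2, 0.95, 3),
        np.linalg.cholesky(0.15 * np.ones((3, 3)) + 0.35 * np.eye(3)),
    )
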