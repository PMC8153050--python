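import dataclasses

import numpy as np
import pytest

from urgewave import CohortConfig


@pytest.fixture
def small_config() -> CohortConfig:
    """Shrunk cohort for fast integration tests (not an acceptance surrogate)."""
    return dataclasses.replace(
        CohortConfig(), n_subjects=4, block_duration_s=120.0
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
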