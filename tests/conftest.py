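import numpy as np
import pytest

from gma import (CohortSpec, build_all_matrices, clean_session, filter_session,
                 generate_cohort, segment_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A 5-subject cohort short enough for fast feature tests (10 frames)."""
    spec = CohortSpec(n_normal=3, n_low_risk=1, n_high_risk=1,
                      duration_s=240.0, seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_frames(small_cohort):
    return segment_cohort(
        [filter_session(clean_session(s)) for s in small_cohort])


@pytest.fixture(scope="session")
def small_matrices(small_frames):
    return build_all_matrices(small_frames)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
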