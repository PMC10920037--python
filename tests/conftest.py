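import numpy as np
import pytest

from psytraj.cohort import CohortSpec, generate_cohort
from psytraj.preprocessing import TrajectoryTensor, score_table, standardize


@pytest.fixture(scope="session")
def small_cohort():
    """120 participants, default catalog, light missingness."""
    return generate_cohort(CohortSpec(n_participants=120, seed=7))


@pytest.fixture(scope="session")
def small_tensor(small_cohort):
    spec = small_cohort.spec_echo
    scales = score_table(small_cohort.item_table, spec.assessments)
    return standardize(scales, spec.assessments)


@pytest.fixture
def tiny_tensor():
    """Hand-built 4-participant, 2-wave, 2-assessment tensor."""
    values = np.array([
        [[0.0, 1.0], [2.0, np.nan]],
        [[1.0, -1.0], [0.0, 3.0]],
        [[-1.0, 0.0], [1.0, 1.0]],
        [[2.0, 2.0], [np.nan, -1.0]],
    ])
    mask = (~np.isnan(values)).astype(float)
    return TrajectoryTensor(values, mask, np.arange(4), ("T1", "T2"), ("a", "b"))
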