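import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metsmarkov import (
    CohortSpec,
    IntensityParameters,
    compile_cohort,
    example_parameters,
    generate_cohort,
)

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def truth() -> IntensityParameters:
    return example_parameters()


@pytest.fixture(scope="session")
def small_cohort(truth):
    """A 400-subject cohort under the reference truth (annual screens, 3y)."""
    return generate_cohort(CohortSpec(n_subjects=400, seed=12345, params=truth))


@pytest.fixture(scope="session")
def small_compiled(small_cohort):
    return compile_cohort(small_cohort.histories)
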