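import numpy as np
import pytest
from hypothesis import settings

from gripshift import DesignSpec, SimParams, simulate_cohort

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_spec() -> DesignSpec:
    return DesignSpec()


@pytest.fixture(scope="session")
def small_spec() -> DesignSpec:
    """Scaled-down design (2 reps per condition, 31 trials) for fast tests."""
    return DesignSpec(reps_per_condition=2, n_dummy=3, n_total=31)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """Analytic-mode cohort, 14 participants, scaled-down sequences."""
    return simulate_cohort(spec=small_spec, group_sizes=(4, 4, 3, 3),
                           params=SimParams(), seed=11, mode="analytic")


@pytest.fixture(scope="session")
def small_trace_cohort(small_spec):
    """Traces-mode cohort for extraction tests (metrics left NaN)."""
    return simulate_cohort(spec=small_spec, group_sizes=(2, 2, 2, 2),
                           params=SimParams(), seed=7, mode="traces")
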