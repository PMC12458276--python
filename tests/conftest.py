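import pytest

from retrodiff.pipeline import PipelineConfig, run_cohort
from retrodiff.synthetic_cohort import SimulationConfig, simulate_cohort

COHORT_SEED = 11


@pytest.fixture(scope="session")
def cohort_bundle():
    """Noise-free seven-assembly cohort on a 10 Mb genome (~500 insertions)."""
    return simulate_cohort(SimulationConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cohort_result(cohort_bundle):
    return run_cohort(cohort_bundle, PipelineConfig(seed=COHORT_SEED))
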