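import numpy as np
import pytest

from immunoscore import (
    AnalysisConfig,
    ReferenceDistribution,
    SimulationConfig,
    endpoints_table,
    generate_cohort,
    score_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """A default-sized synthetic cohort (n=423) generated once per session."""
    return generate_cohort(SimulationConfig(seed=5))


@pytest.fixture(scope="session")
def scored(default_cohort):
    """(scores table, qc report) for the default cohort."""
    return score_cohort(default_cohort.markers, default_cohort.reference)


@pytest.fixture(scope="session")
def endpoints_df(default_cohort):
    return endpoints_table(default_cohort.patients)


@pytest.fixture(scope="session")
def analysis_config():
    return AnalysisConfig(endpoint="TTR", seed=3)


@pytest.fixture
def uniform_reference():
    """Reference with values 1..100 in each channel: a density of k + 0.5
    scores a mid-rank percentile of exactly k."""
    v = np.arange(1.0, 101.0)
    return ReferenceDistribution({ch: v.copy() for ch in
                                  ("cd3_ct", "cd3_im", "cd8_ct", "cd8_im")})
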