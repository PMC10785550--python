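import numpy as np
import pytest

from nichede.bench import _truth_mu, pipeline_on_fixture
from nichede.simulate import SimConfig, generate_fixture, simulate_null_counts


@pytest.fixture(scope="session")
def small_fixture():
    """A small spot-resolution fixture shared by pipeline-level tests."""
    return generate_fixture(SimConfig(n_obs=250, n_genes=120, n_types=3, seed=42))


@pytest.fixture(scope="session")
def small_null_results(small_fixture):
    """Fitted results on null counts for the small fixture."""
    mu = _truth_mu(small_fixture)
    counts = simulate_null_counts(mu, 1.0, np.random.default_rng(7))
    from nichede.model import FilterConfig

    return pipeline_on_fixture(
        small_fixture,
        counts,
        bandwidths=[1.5, 3.0],
        filters=FilterConfig(min_total_count=50, min_pair_obs=10, expr_percentile=80),
    )
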