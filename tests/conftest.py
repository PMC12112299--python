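import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cesep.design import (
    FactorSpace,
    ModelSpec,
    build_candidate_set,
    d_optimal,
    default_n_runs,
)

settings.register_profile(
    "cesep",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("cesep")


@pytest.fixture(scope="session")
def fs():
    return FactorSpace.default()


@pytest.fixture(scope="session")
def quad_spec(fs):
    return ModelSpec.full_quadratic(fs.names)


@pytest.fixture(scope="session")
def design25(fs, quad_spec):
    """Default-sized D-optimal design: 20 exchange points + 5 replicates."""
    dm = d_optimal(
        build_candidate_set(fs),
        default_n_runs(quad_spec),
        quad_spec,
        n_replicates=5,
        seed=0,
    )
    dm.factor_space = fs
    return dm


@pytest.fixture(scope="session")
def design30(fs, quad_spec):
    dm = d_optimal(build_candidate_set(fs), 30, quad_spec, n_replicates=5, seed=0)
    dm.factor_space = fs
    return dm


@pytest.fixture
def rng():
    return np.random.default_rng(0)
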