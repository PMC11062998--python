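"""Shared fixtures: small synthetic instances and the scaled study runs.

The scaled two-group and three-group study runs are session-scoped because
several acceptance checks read different metrics off the same replications.
"""

import numpy as np
import pytest

import latdif as ld
from latdif.model_core import ParameterSet, ResponseMatrix

# study controls: quadrature and iteration budget used for all scaled
# simulation runs (documented in docs/methods.md)
STUDY_CONTROLS = ld.EMControls(n_starts=3, max_iter=500, tol=1e-6, Q=21)


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def small_params(rng):
    """Random two-focal-class parameter set on 4 items."""
    J, K = 4, 2
    return ParameterSet(
        a=rng.uniform(0.5, 1.5, J),
        d=rng.normal(0.0, 1.0, J),
        delta=rng.normal(0.0, 0.6, (J, K)),
        nu=np.array([0.5, 0.3, 0.2]),
        mu=np.array([0.0, 0.4, -0.3]),
        sigma2=np.array([1.0, 1.3, 0.8]),
    )


@pytest.fixture
def small_data(rng):
    """8 respondents x 4 items with a few missing cells."""
    y = (rng.random((8, 4)) < 0.5).astype(float)
    observed = rng.random((8, 4)) < 0.9
    observed[:, 0] = True
    return ResponseMatrix(y, observed)


@pytest.fixture(scope="session")
def two_group_study():
    """Scaled two-group study: N=1000, J=25, focal share 0.1, B=20."""
    config = ld.get_scenario("two_group_J25_pi0.1_N1000", seed=1)
    return ld.run_scenario(config, B=20, controls=STUDY_CONTROLS,
                           with_oracle=True)


@pytest.fixture(scope="session")
def three_group_study():
    """Scaled three-group study: N=1000, J=25, B=10."""
    config = ld.get_scenario("three_group_J25_N1000", seed=1)
    return ld.run_scenario(config, B=10, controls=STUDY_CONTROLS,
                           with_oracle=False)
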