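import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import levelflux as lf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_level_spec():
    return lf.make_two_level()


@pytest.fixture(scope="session")
def chain_spec():
    return lf.make_chain(M=5)


@pytest.fixture(scope="session")
def chain_sourced_spec():
    return lf.make_chain(M=5, source=True)


@pytest.fixture(scope="session")
def chain_balanced_traj(chain_spec):
    """Closed 5-level chain relaxed to (near) thermodynamic balance."""
    return lf.evolve(chain_spec, 3000.0, n_samples=600)


@pytest.fixture(scope="session")
def chain_growth_traj(chain_sourced_spec):
    """Reservoir-fed chain growth, geometrically sampled for regime work."""
    t_eval = np.concatenate([[0.0], np.geomspace(2.0, 8000.0, 3000)])
    return lf.evolve(chain_sourced_spec, 8000.0, t_eval=t_eval)
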