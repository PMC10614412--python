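import numpy as np
import pytest

from wmdev import CohortSpec, generate_cohort
from wmdev.synthetic_cohort import null_spec


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort, shared read-only across tests."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    """A no-group-effect cohort (full slopes for ASD, zero offsets)."""
    return generate_cohort(null_spec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def small_spec(seed=0, **overrides):
    """A fast, reduced-size spec for simulation-heavy tests."""
    defaults = dict(n_td=20, n_asd=24, grid_shape=(8, 8, 4), n_bundles=4,
                    affected_bundles=(1, 2, 3), seed=seed)
    defaults.update(overrides)
    return CohortSpec(**defaults)
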