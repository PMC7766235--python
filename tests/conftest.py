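import numpy as np
import pytest

from instance_easytl import CohortSpec, LabeledDomain, gen_cohort


@pytest.fixture(scope="session")
def mini_cohort():
    """Small shifted feature-mode cohort shared by cohort-level tests."""
    spec = CohortSpec(n_subjects=3, windows_per_class=60, seed=7)
    return gen_cohort(spec)


@pytest.fixture(scope="session")
def mini_transfer(mini_cohort):
    """Pooled-source / target pair from the mini cohort."""
    source = LabeledDomain(
        np.vstack([d.X for d in mini_cohort[:2]]),
        np.concatenate([d.y for d in mini_cohort[:2]]),
    )
    return source, mini_cohort[2]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
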