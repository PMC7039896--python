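import numpy as np
import pytest

from cochleaplan import (
    CochlearGeometry,
    InsertionStudy,
    ModelParams,
    default_study_config,
    generate_cohort,
)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture
def geom():
    return CochlearGeometry(A=9.2, B=6.8)


@pytest.fixture(scope="session")
def default_cohort():
    """One deterministic default-design cohort (n=46, 2 observers x 2 obs)."""
    return generate_cohort(default_study_config(seed=11))


@pytest.fixture(scope="session")
def fitted_default(default_cohort):
    return InsertionStudy.from_cohort(default_cohort).fit()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200224)
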