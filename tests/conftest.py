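import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import discrimbench as db

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_cohort() -> db.Cohort:
    """The default study-like cohort: n=243, three predictors."""
    return db.generate_cohort(db.paper_like(seed=7))


@pytest.fixture(scope="session")
def big_logistic_cohort() -> db.Cohort:
    """Large logistic-regime cohort for parameter-recovery checks."""
    return db.generate_cohort(db.paper_like(seed=11, n=50_000))


@pytest.fixture(scope="session")
def big_lda_cohort() -> db.Cohort:
    """Large shared-covariance Gaussian cohort (LDA's home turf)."""
    return db.generate_cohort(db.lda_paper_like(seed=11, n=20_000))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
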