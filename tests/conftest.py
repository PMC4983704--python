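import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160815)


@pytest.fixture(scope="session")
def small_cohort():
    """A reproducible 30-subject progressive cohort (visits table)."""
    from combiwise.simulate import SyntheticSpec, generate_cohort

    return generate_cohort(SyntheticSpec(n_subjects=30), seed=11)


@pytest.fixture(scope="session")
def balanced_series():
    """Balanced longitudinal data with known variance components."""
    rng = np.random.default_rng(7)
    m, months = 12, np.array([-12.0, -6.0, 0.0])
    b = rng.normal(0, 1.5, m)
    y = 40.0 + 0.25 * months + b[:, None] + rng.normal(0, 1.0, (m, 3))
    return (
        np.repeat([f"S{i:02d}" for i in range(m)], 3),
        np.tile(months, m),
        y.ravel(),
        y,
        months,
    )
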