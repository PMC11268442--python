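import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methylgrowth import CohortConfig, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """48-child cord-blood cohort with 5 planted gene effects."""
    return simulate_cohort(CohortConfig(n_samples=48, n_genes=60, seed=11))


@pytest.fixture(scope="session")
def placenta_cohort():
    return simulate_cohort(CohortConfig(n_samples=48, n_genes=60,
                                        tissue="placenta", seed=11))


@pytest.fixture(scope="session")
def pheno20():
    """Deterministic 20-child anthropometrics fixture."""
    rng = np.random.default_rng(7)
    n = 20
    waz_b = rng.normal(size=n)
    laz_b = 0.5 * waz_b + rng.normal(size=n)
    laz_6 = 0.6 * laz_b + rng.normal(size=n)
    age = 182 + rng.normal(0, 7, size=n)
    waz_6 = 0.5 * waz_b + 0.2 * laz_6 + rng.normal(size=n)
    return pd.DataFrame({
        "sex": np.where(rng.random(n) < 0.5, "female", "male"),
        "weight_birth": 3.3 + 0.45 * waz_b,
        "length_birth": 49.9 + 1.9 * laz_b,
        "weight_6m": 7.7 + 0.8 * waz_6,
        "length_6m": 66 + 2.0 * laz_6,
        "age_6m_days": age,
        "waz_birth": waz_b, "waz_6m": waz_6,
        "laz_birth": laz_b, "laz_6m": laz_6,
    }, index=[f"C{i:02d}" for i in range(n)])
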