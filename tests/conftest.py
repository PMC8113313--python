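import numpy as np
import pandas as pd
import pytest

from radphen.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient cohort with strong planted structure, shared read-only."""
    cfg = CohortConfig(
        n_tumors=40,
        n_features=60,
        k_feature_clusters=5,
        phenotype_shift=4.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def surv_frame():
    """Simulated survival records with a known ln-2 binary effect."""
    rng = np.random.default_rng(42)
    n = 200
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (0.01 * np.exp(np.log(2.0) * x)))
    c = np.minimum(rng.exponential(150.0, n), 500.0)
    return pd.DataFrame(
        {"time": np.minimum(t, c), "event": (t <= c).astype(int), "x": x}
    )
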