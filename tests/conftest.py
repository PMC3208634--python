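import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from sdinet import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-patient default cohort shared across read-only tests."""
    return synthetic.generate_cohort(synthetic.CohortConfig(n_patients=2000, seed=11))


def planted_dataset(n: int, seed: int, n_vars: int = 20, n_informative: int = 3,
                    beta: float = 1.5):
    """Binary design with the first ``n_informative`` variables carrying a
    planted log-odds effect; the rest are pure noise."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, n_vars)) < 0.4).astype(float)
    eta = -1.0 + beta * X[:, :n_informative].sum(axis=1)
    y = (rng.random(n) < expit(eta)).astype(int)
    cols = [f"v{i:02d}" for i in range(n_vars)]
    return pd.DataFrame(X, columns=cols), y
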