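import numpy as np
import pytest

from radstrat import synthdata as sd


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across tests (read-only)."""
    cfg = sd.SyntheticConfig(n_patients=80, n_features=8, seed=42)
    lesions, patients, truth = sd.generate_cohort(cfg)
    return cfg, lesions, patients, truth


def gaussian_blobs(seed: int, n_per: int = 20, separation: float = 6.0,
                   n_features: int = 3, k: int = 3):
    """k spherical unit-variance Gaussian blobs, one mean per coordinate axis
    at distance `separation` from the origin (mutual distance sep * sqrt(2))."""
    assert k <= n_features
    rng = np.random.default_rng(seed)
    means = np.zeros((k, n_features))
    for c in range(k):
        means[c, c] = separation
    X = np.vstack([m + rng.standard_normal((n_per, n_features)) for m in means])
    y = np.repeat(np.arange(k), n_per)
    return X, y
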