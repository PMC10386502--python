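import numpy as np
import pytest

import metaborank as mb


@pytest.fixture(scope="session")
def small_dataset():
    """300 samples, 10 blocks x 10 features, rho=0.7, 3 signal blocks."""
    cfg = mb.SyntheticConfig(n_samples=300, n_blocks=10, block_size=10, rho=0.7,
                             n_signal_blocks=3, beta_signal=1.0, seed=42)
    m, meta = mb.generate_dataset(cfg)
    return cfg, m, meta


@pytest.fixture(scope="session")
def small_scaled(small_dataset):
    cfg, m, meta = small_dataset
    Xs = mb.preprocess(m, meta)
    return cfg, Xs, meta.aligned_to(Xs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230628)
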