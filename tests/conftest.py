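import numpy as np
import pytest

from tabletpred import data_model, synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """Validated synthetic dataset, 80 formulations."""
    cfg = synthetic.SyntheticConfig(n_formulations=80, seed=11)
    ds, truth = synthetic.generate(cfg)
    clean, report = data_model.validate_tables(ds)
    assert report.ok
    return clean, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
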