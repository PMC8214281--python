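import numpy as np
import pytest

import quartetconv as qc


@pytest.fixture(scope="session")
def small_sim():
    """A small three-genome dataset with implanted conversions."""
    cfg = qc.SimConfig(
        n_genes=80, seed=3, wcv_rate=0.1, pcv_rate=0.1,
        loss_rates=(0.05, 0.1, 0.08), donor_bias=1.0,
    )
    return qc.simulate(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """No loss, no conversion: every paralogue pair retained everywhere."""
    cfg = qc.SimConfig(n_genes=40, seed=5, loss_rates=(0.0, 0.0, 0.0))
    return qc.simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
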