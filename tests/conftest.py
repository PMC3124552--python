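import numpy as np
import pandas as pd
import pytest

from tensiomics.synthetic import SynthConfig, generate_expression


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    cfg = SynthConfig(n_genes=400, seed=7)
    expression, samples, truth = generate_expression(cfg)
    return cfg, expression, samples, truth


@pytest.fixture(scope="session")
def null_study():
    """Null-only study (no planted programs) for calibration checks."""
    cfg = SynthConfig(n_genes=2000, frac_planted=0.0, seed=11)
    expression, samples, truth = generate_expression(cfg)
    return cfg, expression, samples, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def toy_zratios():
    """Wide z-ratio table for five genes over the three contrasts."""
    return pd.DataFrame(
        {
            1: [2.0, -1.0, 0.5, 3.0, -2.0],
            4: [1.5, -2.0, -0.5, 2.0, 1.0],
            9: [1.0, -0.5, 0.0, 1.0, -1.5],
        },
        index=[f"g{i}" for i in range(5)],
    )
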