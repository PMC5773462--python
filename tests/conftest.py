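import numpy as np
import pandas as pd
import pytest

from fdgsig.expression import ExpressionMatrix
from fdgsig.synthetic import SyntheticConfig, generate_cohort, generate_validation_cohort


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A fast cohort with a clearly detectable planted signal."""
    return SyntheticConfig(
        n_probes=400,
        n_samples=40,
        n_signal_probes=30,
        n_signal_blocks=3,
        block_rho=0.7,
        effect_size_range=(0.08, 0.2),
        noise_sd=0.3,
        validation_n=10,
        include_influential=False,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_validation(small_cohort, small_config):
    return generate_validation_cohort(small_cohort, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_matrix():
    """4 probes x 5 samples with one probe lacking a gene symbol."""
    values = pd.DataFrame(
        np.arange(20, dtype=float).reshape(4, 5) + np.eye(4, 5) * 3.0,
        index=["p1", "p2", "p3", "p4"],
        columns=[f"s{i}" for i in range(5)],
    )
    symbols = pd.Series(["GA", "GB", None, "GA"], index=values.index)
    return ExpressionMatrix(values=values, gene_symbols=symbols)
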