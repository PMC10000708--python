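import numpy as np
import pandas as pd
import pytest

from tmescorer import CohortConfig, ExpressionMatrix, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with planted structure shared across test modules."""
    cfg = CohortConfig(
        n_samples=120,
        n_genes=400,
        genes_per_signature=6,
        n_planted_degs=60,
        seed=7,
    )
    return cfg, *generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_expression(rng):
    def make(n_genes=100, n_samples=20, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        vals = r.gamma(2.0, 50.0, size=(n_genes, n_samples))
        df = pd.DataFrame(
            vals,
            index=[f"G{i:04d}" for i in range(n_genes)],
            columns=[f"S{j:03d}" for j in range(n_samples)],
        )
        return ExpressionMatrix(df, "TPM")

    return make
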