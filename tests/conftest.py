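import numpy as np
import pandas as pd
import pytest

from rfi_coexnet.expression import ExpressionMatrix
from rfi_coexnet.synthetic import ExpressionSimConfig, simulate_expression


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    """10 genes x 8 samples of positive expression values."""
    vals = rng.lognormal(mean=3.0, sigma=0.6, size=(10, 8))
    return ExpressionMatrix(
        values=pd.DataFrame(
            vals,
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(8)],
        ),
        unit="TPM",
    )


def planted_dataset(seed, module_sizes=(100, 80, 60), cors=(0.54, -0.48, 0.0),
                    n_genes=600, n_samples=50):
    """Planted-module expression with a trait, small enough for tests."""
    rng = np.random.default_rng(1000 + seed)
    trait = rng.standard_normal(n_samples)
    cfg = ExpressionSimConfig(
        n_genes=n_genes, n_samples=n_samples,
        module_sizes=module_sizes, module_trait_cor=cors, seed=seed,
    )
    expr, truth = simulate_expression(cfg, trait)
    return expr, truth, trait
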