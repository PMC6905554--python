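import numpy as np
import pandas as pd
import pytest

import ocgene as og


@pytest.fixture(scope="session")
def gaussian_cloud():
    rng = np.random.default_rng(7)
    return rng.normal(size=(100, 2))


@pytest.fixture(scope="session")
def small_synthetic():
    """Small synthetic benchmark: 300 genes, 12+12 samples, strong effect."""
    cfg = og.SyntheticConfig(
        n_genes=300,
        n_disease_samples=12,
        n_healthy_samples=12,
        disease_gene_fraction=0.3,
        effect_size_delta=3.0,
        noise_sd=1.0,
        contamination_fraction=0.1,
        seed=11,
    )
    expr, truth = og.generate_expression(cfg)
    return cfg, expr, truth


@pytest.fixture(scope="session")
def small_benchmark(small_synthetic):
    _, expr, truth = small_synthetic
    de = og.differential_expression(expr)
    return og.select_positive_unlabeled(de, expr.values)


@pytest.fixture
def toy_expression():
    """One clearly differential gene, one flat gene, on log2 scale."""
    values = pd.DataFrame(
        {
            "d1": [8.0, 5.0],
            "d2": [9.0, 5.0],
            "d3": [10.0, 5.0],
            "h1": [2.0, 5.0],
            "h2": [3.0, 5.0],
            "h3": [4.0, 5.0],
        },
        index=["gA", "gB"],
    )
    condition = pd.Series(
        ["disease"] * 3 + ["healthy"] * 3, index=values.columns, name="condition"
    )
    return og.ExpressionMatrix(values=values, condition=condition)
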