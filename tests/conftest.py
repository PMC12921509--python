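import numpy as np
import pandas as pd
import pytest

import scembed as se


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_expression(rng):
    """10 cells x 6 genes of normalized log expression with metadata."""
    values = rng.gamma(2.0, 1.0, size=(10, 6))
    cells = [f"c{i}" for i in range(10)]
    genes = [f"g{j}" for j in range(6)]
    meta = pd.DataFrame(
        {
            "cell_type": ["A"] * 5 + ["B"] * 5,
            "batch": ["b0", "b1"] * 5,
            "condition": ["control"] * 5 + ["disease"] * 5,
        },
        index=pd.Index(cells, name="cell_id"),
    )
    return se.ExpressionMatrix(values, cells, genes, meta, normalized=True)


@pytest.fixture()
def small_table(rng):
    genes = [f"g{j}" for j in range(6)]
    return se.FeatureEmbeddingTable(genes, rng.standard_normal((6, 5)))


@pytest.fixture(scope="session")
def zero_shot_dataset():
    """The 600-cell, 200-gene, 4-type reference dataset (seed 0)."""
    spec = se.SynthSpec(seed=0)
    feats, groups = se.synth_feature_embeddings(spec)
    x, truth = se.synth_expression(spec)
    return spec, feats, groups, x, truth


@pytest.fixture(scope="session")
def disease_dataset():
    """Planted-driver disease dataset (seed 0, one driver, effect 3)."""
    spec = se.SynthSpec(seed=0, planted_driver_genes=1, driver_effect=3.0)
    feats, _ = se.synth_feature_embeddings(spec)
    x, drivers = se.synth_disease(spec)
    return spec, feats, x, drivers
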