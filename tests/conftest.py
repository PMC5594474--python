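import numpy as np
import pandas as pd
import pytest

from icastab import ExpressionMatrix, GeneratorConfig, generate_factor_data


@pytest.fixture(scope="session")
def small_factor_data():
    """Planted 5-source data small enough for per-test decompositions."""
    cfg = GeneratorConfig(
        n_genes=400,
        n_samples=80,
        k_sources=5,
        n_weak_programs=0,
        seed=11,
    )
    return generate_factor_data(cfg)


@pytest.fixture
def tiny_expression():
    rng = np.random.default_rng(3)
    values = rng.normal(size=(30, 12))
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(30)],
        [f"s{j}" for j in range(12)],
    )


@pytest.fixture
def expression_tsv(tmp_path):
    frame = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.5], [0.5, -1.0]],
        index=["tp53", "brca1", "myc"],
        columns=["sampleA", "sampleB"],
    )
    path = tmp_path / "expr.tsv"
    frame.to_csv(path, sep="\t", index_label="gene")
    return path, frame
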