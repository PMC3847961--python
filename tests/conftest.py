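import numpy as np
import pytest

from clrnet import ExpressionMatrix


def random_expression(n_genes: int, n_samples: int, seed: int) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_genes, n_samples))
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{j:03d}" for j in range(n_samples)]
    return ExpressionMatrix(genes, samples, values)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    return random_expression(6, 12, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
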