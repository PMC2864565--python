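import numpy as np
import pytest

from tmmnorm import CountMatrix


def random_count_matrix(
    rng: np.random.Generator,
    n_genes: int = 200,
    n_libs: int = 2,
    mean: float = 200.0,
) -> CountMatrix:
    """A heavy-tailed random count matrix with no all-zero pathologies."""
    base = rng.lognormal(mean=np.log(mean), sigma=1.5, size=n_genes)
    counts = rng.poisson(base[:, None] * rng.uniform(0.5, 2.0, size=n_libs))
    return CountMatrix(
        gene_ids=tuple(f"g{i}" for i in range(n_genes)),
        library_ids=tuple(f"lib{j}" for j in range(n_libs)),
        counts=counts,
    )


@pytest.fixture
def small_counts() -> CountMatrix:
    return CountMatrix(
        gene_ids=("g1", "g2", "g3"),
        library_ids=("L1", "L2"),
        counts=np.array([[10, 20], [100, 100], [0, 5]]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
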