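import numpy as np
import pytest

from ergcn import ExpressionMatrix, SubtypeLabels, default_benchmark

# Mid-point between the benchmark's between-class (~0.33) and within-class
# (~0.65) correlation levels; at this threshold the similarity graph separates
# the four subtypes cleanly.
BENCHMARK_THETA = 0.5


@pytest.fixture(scope="session")
def benchmark():
    return default_benchmark()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_expr():
    rng = np.random.default_rng(7)
    return ExpressionMatrix(
        sample_ids=tuple(f"s{i}" for i in range(6)),
        gene_ids=tuple(f"g{j}" for j in range(10)),
        values=rng.normal(size=(6, 10)),
    )


@pytest.fixture
def tiny_labels():
    return SubtypeLabels(
        sample_ids=tuple(f"s{i}" for i in range(6)),
        labels=np.array([0, 0, 1, 1, 0, 1]),
        class_names=("A", "B"),
    )


def random_adjacency(rng: np.random.Generator, m: int, p: float = 0.3) -> np.ndarray:
    A = (rng.random((m, m)) < p).astype(float)
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 1.0)
    return A
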