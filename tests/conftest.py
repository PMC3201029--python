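import numpy as np
import pytest

from famalign.core_io import ALPHABET, GapPenalties, SimilarityMatrix, load_builtin_matrix
from famalign.synthetic import distinct_family_models, make_benchmark, random_family_model


@pytest.fixture(scope="session")
def vtml200():
    return load_builtin_matrix("vtml200")


@pytest.fixture(scope="session")
def blosum50():
    return load_builtin_matrix("blosum50")


def random_matrix(rng: np.random.Generator, low: int = -6, high: int = 9) -> SimilarityMatrix:
    raw = rng.integers(low, high, size=(20, 20))
    sym = np.triu(raw) + np.triu(raw, 1).T
    return SimilarityMatrix("random", sym)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def benchmark3():
    """Seeded 3-family benchmark: 12 pairs per family, known truth."""
    models = [random_family_model(f"fam{k}", seed=100 + k, identity=0.7) for k in range(3)]
    return make_benchmark(models, pairs_per_family=12, seed=7, mean_len=100)


@pytest.fixture(scope="session")
def benchmark_discrim():
    """Harder benchmark for discrimination checks: disjoint family
    compositions, lower identity, more data per family."""
    models = distinct_family_models(3, seed=21, identity=0.5)
    return make_benchmark(models, pairs_per_family=24, seed=21, mean_len=150)


@pytest.fixture(scope="session")
def default_penalties():
    return GapPenalties(15, 1)
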