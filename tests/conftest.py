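import numpy as np
import pytest
from hypothesis import settings

from mirhairpin import PotentialSet, fold_many, make_benchmark

settings.register_profile("suite", max_examples=50, deadline=None,
                          derandomize=True)
settings.load_profile("suite")


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_benchmark():
    """40+40 easy benchmark, folded once and shared across tests."""
    pos, neg = make_benchmark(40, 40, difficulty=0.1, seed=7)
    return fold_many(pos, engine="auto"), fold_many(neg, engine="auto")


@pytest.fixture(scope="session")
def trained_tables(small_benchmark):
    pos_pairs, neg_pairs = small_benchmark
    return PotentialSet.train(pos_pairs, neg_pairs)
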