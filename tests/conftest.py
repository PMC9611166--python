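import numpy as np
import pytest

from cocrystal_gcn import (
    Hyperparameters,
    ModelParams,
    SyntheticSpec,
    build_pair_graph,
    generate_library,
)


@pytest.fixture(scope="session")
def small_library() -> list[str]:
    """60 synthetic molecules (donor / acceptor / motif-free mix)."""
    return generate_library(SyntheticSpec(n_molecules=60, seed=7))


@pytest.fixture(scope="session")
def random_pairs(small_library):
    """100 random API/coformer pair graphs from the synthetic library."""
    rng = np.random.default_rng(42)
    pairs = []
    for _ in range(100):
        i, j = rng.choice(len(small_library), size=2, replace=False)
        pairs.append(build_pair_graph(small_library[i], small_library[j]))
    return pairs


@pytest.fixture()
def tiny_params() -> ModelParams:
    """Randomly initialized small network for forward/attribution tests."""
    hp = Hyperparameters(embed_dim1=8, embed_dim2=8, fc_hidden=8, epochs=1)
    return ModelParams.initialize(hp, seed=123)
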