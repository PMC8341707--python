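import numpy as np
import pytest

from elate import (
    AEConfig,
    GeneratorConfig,
    RepertoireSample,
    TCRClone,
    build_scheme,
    generate_repertoire,
    train,
)


@pytest.fixture(scope="session")
def host_samples():
    """Two hosts x two samples, 300 clones each, seeded shared public pools."""
    cfg = GeneratorConfig(
        n_samples=4, clones_per_sample=300, n_hosts=2, public_pool_size=120, sharing_probability=0.8, seed=42
    )
    return generate_repertoire(cfg)


@pytest.fixture(scope="session")
def scheme(host_samples):
    return build_scheme(host_samples)


@pytest.fixture(scope="session")
def scheme_v(host_samples):
    return build_scheme(host_samples, use_v=True)


@pytest.fixture(scope="session")
def small_trained_e(host_samples, scheme):
    """A briefly trained E model: embeddings are structured but training is cheap."""
    return train(host_samples, scheme, AEConfig(epochs=30, seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_clones(rng: np.random.Generator, n: int, min_len: int = 6, max_len: int = 16) -> list[TCRClone]:
    """Uniform random valid clones for round-trip style checks."""
    from elate.io_encoding import AA_ALPHABET

    clones = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        clones.append(TCRClone(cdr3="".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))))
    return clones
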