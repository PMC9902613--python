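import numpy as np
import pytest

from dnacodec import (
    Codebook,
    ConcatenationScheme,
    ConstraintSpec,
    build_model,
    generate_codebook,
)


@pytest.fixture(scope="session")
def uniform_codebook():
    """All four 1-mers: the constraint-free codebook (2 bits/base)."""
    return Codebook(["A", "C", "G", "T"])


@pytest.fixture(scope="session")
def uniform_model(uniform_codebook):
    return build_model(uniform_codebook)


@pytest.fixture(scope="session")
def no_gg_model(uniform_codebook):
    """Two-state model forbidding consecutive G's (1-mer words, GG junction rule)."""
    return build_model(uniform_codebook, ConcatenationScheme({"G": ["G"]}))


@pytest.fixture(scope="session")
def small_constrained():
    """n=4 codebook with hp_max=2 and 25-75% GC per word, plus its scheme."""
    spec = ConstraintSpec(gc_min=0.25, gc_max=0.75, gc_interval=4, hp_max=2)
    cb, scheme = generate_codebook(spec, 4)
    return spec, cb, scheme


@pytest.fixture(scope="session")
def small_model(small_constrained):
    _, cb, scheme = small_constrained
    return build_model(cb, scheme)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
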