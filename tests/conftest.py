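import numpy as np
import pytest

from typeslip import CharNGramLM, KeyboardLayout, default_resources, load_layout


@pytest.fixture(scope="session")
def en_layout():
    return load_layout("en")


@pytest.fixture(scope="session")
def es_layout():
    return load_layout("es")


@pytest.fixture(scope="session")
def resources():
    """Packaged layouts, stimuli and trained language models (cached)."""
    res = default_resources()
    res.lm("en"), res.lm("es")  # warm the caches once per session
    return res


@pytest.fixture(scope="session")
def en_lm(resources):
    return resources.lm("en")


@pytest.fixture(scope="session")
def tiny_lm():
    """Order-3 model on a 6-line toy corpus; small enough to reason about."""
    corpus = ["the cat sat on the mat", "the dog sat on the log",
              "a cat and a dog", "the cat ran", "the dog ran", "on the mat"]
    return CharNGramLM.train(corpus, order=3)


@pytest.fixture(scope="session")
def grid_layout():
    """A tiny fully synthetic 3x4 grid layout for closed-form distance checks."""
    keys = "abcd" "efgh" "ijkl"
    positions = {k: (divmod(i, 4)) for i, k in enumerate(keys)}
    return KeyboardLayout("toy", positions, {"A": "a", "É": "e"})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
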