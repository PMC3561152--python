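import pytest

from negev.cue_lexicon import load_lexicon
from negev.synthetic_corpus import GeneratorConfig, generate

# fixed study conditions for the end-to-end suites
BIG_SEED = 424242
BIG_N = 10_000


@pytest.fixture(scope="session")
def c40():
    return load_lexicon("c40")


@pytest.fixture(scope="session")
def small_corpus():
    """A 400-sentence corpus under default conditions, for unit/property tests."""
    cfg = GeneratorConfig(n_sentences=400, seed=101)
    return generate(cfg)


@pytest.fixture(scope="session")
def big_corpus():
    """The 10,000-sentence default-condition corpus used for the
    end-to-end recovery and distribution checks."""
    cfg = GeneratorConfig(n_sentences=BIG_N, seed=BIG_SEED)
    return cfg, generate(cfg)
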