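import numpy as np
import pytest

from nevex.corpus import load_corpus
from nevex.synthetic import GeneratorConfig, generate, write_corpus

# reduced model geometry used throughout the tests: same architecture as the
# full configuration, scaled to single-CPU runtimes
SMALL_MODEL = dict(
    contextual_dim=24,
    pos_dim=6,
    entity_dim=6,
    lstm_hidden=24,
    tagger_hidden=48,
    attention_heads=2,
    batch_size=1,
    learning_rate=0.2,
    dice_beta=0.3,
)


@pytest.fixture(scope="session")
def toy_corpus(tmp_path_factory):
    """The default 50-sentence corpus (10 docs x 5 sentences, seed 7)."""
    cfg = GeneratorConfig(n_docs=10, sentences_per_doc=5, seed=7)
    out = tmp_path_factory.mktemp("toy_corpus")
    corpus = generate(cfg)
    write_corpus(corpus, out)
    docs, examples, dropped = load_corpus(out)
    return {"cfg": cfg, "corpus": corpus, "dir": out, "docs": docs,
            "examples": examples, "dropped": dropped}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
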