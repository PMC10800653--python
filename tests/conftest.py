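import numpy as np
import pytest

import lexlearn as ll


@pytest.fixture
def toy_lexicon() -> ll.Lexicon:
    """Three Dutch-flavoured words with descending frequencies."""
    return ll.Lexicon(
        [
            ll.LexiconEntry("aap", "aap", 3),
            ll.LexiconEntry("noot", "noot", 1),
            ll.LexiconEntry("mies", "mies", 0),
        ]
    )


@pytest.fixture
def planted_system():
    """A consistent noise-free linear system over a small lexicon."""
    cfg = ll.GeneratorConfig(seed=42, m=30, q=6, noise_sd=0.0,
                             alphabet="abcdefghijklmnop", word_length=(4, 7))
    lex = ll.generate_lexicon(cfg)
    C = ll.build_cue_matrix(lex, n=2)
    S, F_star = ll.generate_semantics(lex, C, cfg)
    return lex, C, S, F_star


@pytest.fixture
def noisy_zipf_system():
    """The default Zipfian noise-bearing study conditions, scaled down."""
    cfg = ll.GeneratorConfig(seed=11, m=120)
    lex = ll.generate_lexicon(cfg)
    C = ll.build_cue_matrix(lex, n=2)
    S, _ = ll.generate_semantics(lex, C, cfg)
    return lex, C, S


def random_weighted_instance(rng: np.random.Generator):
    """A random small weighted-regression instance (for oracle checks)."""
    m = int(rng.integers(3, 51))
    r = int(rng.integers(2, 41))
    q = int(rng.integers(1, 11))
    X = (rng.random((m, r)) < 0.3).astype(float)
    X[X.sum(axis=1) == 0, rng.integers(r)] = 1.0
    Y = rng.standard_normal((m, q))
    f = rng.integers(0, 21, size=m)
    if not (f > 0).any():
        f[rng.integers(m)] = 1
    return X, Y, f
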