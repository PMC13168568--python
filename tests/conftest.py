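import numpy as np
import pytest

import speechtrf as st


@pytest.fixture(scope="session")
def toy_lexicon():
    """The 3-word worked-example lexicon: {ba:2, bi:1, da:1}."""
    return st.make_lexicon([("ba", "b a", 2), ("bi", "b i", 1),
                            ("da", "d a", 1)])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_lexicon(rng, max_words=50, alphabet="abcd", max_len=4):
    """Random small lexicon for oracle-equivalence checks."""
    n = int(rng.integers(1, max_words + 1))
    entries = {}
    for _ in range(n):
        length = int(rng.integers(1, max_len + 1))
        phon = tuple(rng.choice(list(alphabet), size=length))
        form = "".join(phon)
        freq = int(rng.integers(1, 20))
        entries[(form, phon)] = entries.get((form, phon), 0) + freq
    return st.make_lexicon([(f, p, q) for (f, p), q in sorted(entries.items())])


# --- independent brute-force cohort oracle -------------------------------

def brute_prefix_mass(lexicon, prefix):
    prefix = tuple(prefix)
    return sum(e.frequency for e in lexicon.entries
               if e.phonemes[:len(prefix)] == prefix)


def brute_conditional_probability(lexicon, prefix, phoneme):
    from fractions import Fraction
    old = brute_prefix_mass(lexicon, prefix)
    new = brute_prefix_mass(lexicon, tuple(prefix) + (phoneme,))
    return Fraction(new, old) if new else None


def brute_next_entropy(lexicon, prefix, include_word_end=True):
    import math
    prefix = tuple(prefix)
    dist = {}
    for e in lexicon.entries:
        if e.phonemes[:len(prefix)] != prefix:
            continue
        if len(e.phonemes) > len(prefix):
            key = e.phonemes[len(prefix)]
        elif include_word_end:
            key = "#end#"
        else:
            continue
        dist[key] = dist.get(key, 0) + e.frequency
    total = sum(dist.values())
    return -sum(m / total * math.log2(m / total) for m in dist.values())
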