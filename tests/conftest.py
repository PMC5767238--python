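from functools import lru_cache

import numpy as np
import pytest

from langsample import Token, CUnit, Transcript, default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def make_simple_transcript(words, participant="p1", visit="v1", duration=30.0):
    """A one-C-unit transcript of plain nouns; handy for alignment tests."""
    tokens = [Token(w, w, "noun") for w in words]
    return Transcript(
        participant_id=participant,
        visit_id=visit,
        duration_s=duration,
        cunits=[CUnit(tokens=tokens)],
    )


def brute_force_agreement(a, b):
    """Independent alignment oracle: recursive search over all alignments,
    minimizing (edit cost, -matches, length) lexicographically."""
    a, b = tuple(a), tuple(b)

    @lru_cache(maxsize=None)
    def go(i, j):
        if i == len(a) and j == len(b):
            return (0, 0, 0)
        options = []
        if i < len(a) and j < len(b):
            c, m, L = go(i + 1, j + 1)
            hit = a[i] == b[j]
            options.append((c + (0 if hit else 1), m - (1 if hit else 0), L + 1))
        if i < len(a):
            c, m, L = go(i + 1, j)
            options.append((c + 1, m, L + 1))
        if j < len(b):
            c, m, L = go(i, j + 1)
            options.append((c + 1, m, L + 1))
        return min(options)

    cost, neg_matches, length = go(0, 0)
    return 100.0 * (-neg_matches) / length


def random_token_pair(rng, max_len=12, alphabet=("a", "b", "c", "d")):
    """Two related token sequences differing by random edits."""
    n = int(rng.integers(1, max_len + 1))
    a = [str(rng.choice(alphabet)) for _ in range(n)]
    b = list(a)
    for _ in range(int(rng.integers(0, 4))):
        op = rng.integers(0, 3)
        pos = int(rng.integers(0, max(len(b), 1)))
        if op == 0 and b:
            b[pos % len(b)] = str(rng.choice(alphabet))
        elif op == 1 and len(b) < max_len:
            b.insert(pos, str(rng.choice(alphabet)))
        elif op == 2 and len(b) > 1:
            del b[pos % len(b)]
    return a, b
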