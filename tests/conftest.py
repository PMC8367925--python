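"""Shared fixtures: toy lexicons and session-scoped experiment runs.

The interactive-activation experiment on the default synthetic setup takes
a few seconds, so it is run once per session and shared between the
experiment tests and the acceptance tests.
"""

from __future__ import annotations

import pytest

from predlex import experiment as xp
from predlex.lexicon import LexicalEntry, Lexicon, PhonemeInventory
from predlex.synthetic_data import (
    LexiconSpec,
    TripleSpec,
    generate_lexicon,
    generate_triples,
)


def make_lexicon(words: dict[str, float], symbols: str | None = None) -> Lexicon:
    """Build a lexicon from ``{"abc": freq}`` with one-char phonemes."""
    if symbols is None:
        symbols = "".join(sorted({c for w in words for c in w}))
    inv = PhonemeInventory(tuple(symbols))
    entries = [LexicalEntry(tuple(w), f) for w, f in words.items()]
    return Lexicon(entries, inv)


@pytest.fixture
def tiny_lexicon() -> Lexicon:
    # phonologically clustered toy vocabulary: a "for-" cohort plus filler
    return make_lexicon(
        {
            "formjula": 30.0,
            "forbid": 10.0,
            "foresta": 5.0,
            "mushroom": 20.0,
            "mud": 8.0,
        }
    )


@pytest.fixture(scope="session")
def default_lexicon() -> Lexicon:
    return generate_lexicon(LexiconSpec(seed=1))


@pytest.fixture(scope="session")
def default_triples(default_lexicon):
    return generate_triples(default_lexicon, TripleSpec(n_triples=15, seed=2))


@pytest.fixture(scope="session")
def prediction_results(default_lexicon, default_triples):
    return xp.run_counterbalanced(default_lexicon, default_triples, model="prediction")


@pytest.fixture(scope="session")
def iam_results(default_lexicon, default_triples):
    return xp.run_counterbalanced(default_lexicon, default_triples, model="iam")
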