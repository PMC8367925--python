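"""Synthetic lexicons and item triples with the structure the analysis assumes.

Generates vocabularies over a fixed phoneme inventory with variable word
length and Zipf-distributed frequencies, plus source/novel/baseline triples
that share a prefix up to a controllable deviation point, with both nonwords
guaranteed absent from the lexicon.  Everything is deterministic given the
spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lexicon import Form, ItemTriple, LexicalEntry, Lexicon, PhonemeInventory

__all__ = ["LexiconSpec", "TripleSpec", "generate_lexicon", "generate_triples",
           "default_inventory"]

# Opaque phoneme-like labels; single characters so forms print compactly.
_BASE_SYMBOLS = "pbtdkgszfvmnlrwjhaeiou^SZCNEIOU"

_MAX_ATTEMPTS_PER_ITEM = 1000


def default_inventory(size: int) -> PhonemeInventory:
    """A deterministic inventory of ``size`` distinct symbols."""
    if size < 1:
        raise ValueError("inventory size must be >= 1")
    symbols = list(_BASE_SYMBOLS[:size])
    for i in range(len(symbols), size):
        symbols.append(f"q{i}")
    return PhonemeInventory(tuple(symbols))


@dataclass(frozen=True)
class LexiconSpec:
    """Parameters for :func:`generate_lexicon`.

    ``length_weights`` (optional) weights the lengths ``min_len..max_len``;
    uniform when omitted.  Frequencies follow a rank-frequency power law
    ``f(r) = 1000 * r ** -zipf_exponent``.

    ``prefix_reuse`` controls cohort density: with this probability a new
    word copies the first 1..``max_reuse_len`` phonemes of an existing word
    before completing at random.  Natural lexicons share onsets heavily, and
    the deviation-point analyses assume such cohort structure (competitors
    consistent with a partial input); fully i.i.d. phoneme strings would
    make cohorts beyond two phonemes vanishingly rare.
    """

    n_words: int = 240
    inventory_size: int = 10
    min_len: int = 3
    max_len: int = 6
    length_weights: tuple[float, ...] | None = (0.35, 0.3, 0.15, 0.2)
    zipf_exponent: float = 1.0
    prefix_reuse: float = 0.5
    max_reuse_len: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_words < 1:
            raise ValueError("n_words must be >= 1")
        if self.inventory_size < 3:
            raise ValueError("inventory_size must be >= 3")
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")
        if not 0 <= self.prefix_reuse <= 1:
            raise ValueError("prefix_reuse must be in [0, 1]")
        if self.max_reuse_len < 1:
            raise ValueError("max_reuse_len must be >= 1")
        if self.length_weights is not None:
            if len(self.length_weights) != self.max_len - self.min_len + 1:
                raise ValueError("length_weights must have one weight per length")
            if any(w < 0 for w in self.length_weights) or sum(self.length_weights) <= 0:
                raise ValueError("length_weights must be non-negative, not all zero")


@dataclass(frozen=True)
class TripleSpec:
    """Parameters for :func:`generate_triples`.

    ``dp_offset_from_end`` is how many positions before item offset the
    deviation point falls, so ``dp = source_length - dp_offset_from_end``.
    With equal-length items the triple invariant (three-way divergence at
    ``dp + 1``) requires an offset of at least 1.
    """

    n_triples: int = 15
    source_length: int = 6
    dp_offset_from_end: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_triples < 1:
            raise ValueError("n_triples must be >= 1")
        if not 1 <= self.dp_offset_from_end <= 3:
            raise ValueError("dp_offset_from_end must be in 1..3")
        if self.dp_offset_from_end >= self.source_length:
            raise ValueError("dp_offset_from_end must be < source_length")

    @property
    def dp(self) -> int:
        return self.source_length - self.dp_offset_from_end


def _capacity(inventory_size: int, min_len: int, max_len: int) -> float:
    return sum(float(inventory_size) ** length for length in range(min_len, max_len + 1))


def generate_lexicon(spec: LexiconSpec) -> Lexicon:
    """Draw ``spec.n_words`` distinct forms with Zipf-ranked frequencies.

    Forms are random phoneme strings over the inventory, with onset sharing
    injected by the ``prefix_reuse`` process (see :class:`LexiconSpec`);
    there are no further phonotactic constraints.  Frequency rank is
    assigned in draw order, which is itself random.  Deterministic given
    ``spec.seed``.
    """
    if _capacity(spec.inventory_size, spec.min_len, spec.max_len) < spec.n_words:
        raise ValueError(
            f"inventory/length budget cannot host {spec.n_words} distinct forms"
        )
    inventory = default_inventory(spec.inventory_size)
    symbols = list(inventory)
    rng = np.random.default_rng(spec.seed)
    lengths = np.arange(spec.min_len, spec.max_len + 1)
    weights = None
    if spec.length_weights is not None:
        weights = np.asarray(spec.length_weights, dtype=float)
        weights = weights / weights.sum()

    forms: list[Form] = []
    seen: set[Form] = set()
    attempts_left = _MAX_ATTEMPTS_PER_ITEM * spec.n_words
    while len(forms) < spec.n_words:
        if attempts_left <= 0:
            raise ValueError(
                "could not draw enough distinct forms within the attempt budget"
            )
        attempts_left -= 1
        length = int(rng.choice(lengths, p=weights))
        if forms and rng.random() < spec.prefix_reuse:
            donor = forms[int(rng.integers(len(forms)))]
            k_max = min(len(donor), length - 1, spec.max_reuse_len)
            k = int(rng.integers(1, k_max + 1))
            form = donor[:k] + tuple(
                symbols[i] for i in rng.integers(0, len(symbols), size=length - k)
            )
        else:
            form = tuple(
                symbols[i] for i in rng.integers(0, len(symbols), size=length)
            )
        if form in seen:
            continue
        seen.add(form)
        forms.append(form)

    entries = [
        LexicalEntry(form, 1000.0 * (rank + 1) ** -spec.zipf_exponent)
        for rank, form in enumerate(forms)
    ]
    return Lexicon(entries, inventory)


def generate_triples(lex: Lexicon, spec: TripleSpec) -> list[ItemTriple]:
    """Build item triples whose sources are drawn from ``lex``.

    Nonwords copy the source up to the DP and replace the final
    ``dp_offset_from_end`` phonemes; at position ``dp + 1`` the two
    replacement phonemes are sampled uniformly excluding the source's
    phoneme and each other, guaranteeing three-way divergence.  Both
    nonwords are checked absent from ``lex`` (and from all other generated
    forms); infeasible specs error out after a bounded number of attempts.
    """
    rng = np.random.default_rng(spec.seed)
    symbols = list(lex.inventory)
    if len(symbols) < 3:
        raise ValueError("inventory must have >= 3 symbols for three-way divergence")
    dp = spec.dp

    eligible = [f for f in lex.forms if len(f) == spec.source_length]
    # Chosen sources must have distinct pre-DP prefixes, so each triple's
    # prefix identifies it during DP-aligned analysis.
    order = rng.permutation(len(eligible))
    sources: list[Form] = []
    prefixes: set[Form] = set()
    for i in order:
        form = eligible[i]
        if form[:dp] not in prefixes:
            prefixes.add(form[:dp])
            sources.append(form)
        if len(sources) == spec.n_triples:
            break
    if len(sources) < spec.n_triples:
        raise ValueError(
            f"only {len(sources)} eligible sources with distinct prefixes for "
            f"{spec.n_triples} requested triples"
        )

    taken: set[Form] = set(lex.forms)
    triples: list[ItemTriple] = []
    for source in sources:
        for _ in range(_MAX_ATTEMPTS_PER_ITEM):
            candidates = [s for s in symbols if s != source[dp]]
            idx = rng.choice(len(candidates), size=2, replace=False)
            heads = (candidates[int(idx[0])], candidates[int(idx[1])])
            nonwords = []
            for head in heads:
                tail = tuple(
                    symbols[i]
                    for i in rng.integers(
                        0, len(symbols), size=spec.source_length - dp - 1
                    )
                )
                nonwords.append(source[:dp] + (head,) + tail)
            if nonwords[0] in taken or nonwords[1] in taken:
                continue
            triple = ItemTriple(source, nonwords[0], nonwords[1])
            triple.check_against(lex)
            taken.update(nonwords)
            triples.append(triple)
            break
        else:
            raise ValueError(
                "could not construct a valid triple within the attempt budget"
            )
    return triples
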