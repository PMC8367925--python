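"""Vocabulary data model: phoneme inventories, lexicons, item triples, and I/O.

A :class:`Lexicon` maps phoneme-transcribed word forms to frequencies and is
the object that "training" manipulates (adding novel word forms).  An
:class:`ItemTriple` groups a source word with two matched nonwords that share
its onset up to a deviation point (DP), the position after which the three
items diverge.

Positions are 1-based throughout: ``dp`` counts the shared pre-DP phonemes,
so post-DP positions are ``dp + 1``, ``dp + 2``, ... and the DP-relative
position of absolute position ``i`` is ``i - dp`` (pre-DP positions are
<= 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

Form = tuple[str, ...]

__all__ = [
    "PhonemeInventory",
    "LexicalEntry",
    "Lexicon",
    "ItemTriple",
    "triple_deviation_point",
    "uniqueness_point",
    "train_lexicon",
    "read_lexicon",
    "write_lexicon",
    "read_triples",
    "write_triples",
    "LexiconFormatError",
]


class LexiconFormatError(ValueError):
    """Raised when a lexicon or triples file fails to parse or validate."""


@dataclass(frozen=True)
class PhonemeInventory:
    """An ordered set of opaque phoneme labels.

    The order is fixed and defines vector indexing everywhere downstream
    (probability vectors, activation matrices).
    """

    symbols: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise ValueError("inventory must be non-empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("inventory contains duplicate symbols")
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.symbols)}
        )

    @classmethod
    def from_symbols(cls, symbols: Iterable[str]) -> "PhonemeInventory":
        return cls(tuple(symbols))

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"unknown phoneme symbol: {symbol!r}") from None

    def __contains__(self, symbol: object) -> bool:
        return symbol in self._index

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)


@dataclass(frozen=True)
class LexicalEntry:
    """A phoneme-transcribed word form with a non-negative frequency weight."""

    form: Form
    frequency: float
    orthography: str | None = None

    def __post_init__(self) -> None:
        if len(self.form) < 1:
            raise ValueError("form must have length >= 1")
        if not (self.frequency >= 0):
            raise ValueError(f"frequency must be >= 0, got {self.frequency}")

    @property
    def orth(self) -> str:
        return self.orthography if self.orthography is not None else "".join(self.form)


class Lexicon:
    """A collection of lexical entries over one phoneme inventory.

    Duplicate forms are merged by summing frequency (total cohort mass is
    preserved).  Iteration order is insertion order, which read/write
    normalizes to sorted order.
    """

    def __init__(self, entries: Iterable[LexicalEntry], inventory: PhonemeInventory):
        self.inventory = inventory
        self._entries: dict[Form, LexicalEntry] = {}
        for e in entries:
            for p in e.form:
                if p not in inventory:
                    raise LexiconFormatError(
                        f"unknown phoneme symbol: {p!r} in form {' '.join(e.form)}"
                    )
            prev = self._entries.get(e.form)
            if prev is None:
                self._entries[e.form] = e
            else:
                self._entries[e.form] = LexicalEntry(
                    e.form, prev.frequency + e.frequency, prev.orthography
                )
        if self._entries and not self.total_frequency > 0:
            raise ValueError("total lexicon frequency must be > 0")

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[LexicalEntry]:
        return iter(self._entries.values())

    def __contains__(self, form: object) -> bool:
        return form in self._entries

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lexicon):
            return NotImplemented
        return (
            self.inventory == other.inventory
            and {f: e.frequency for f, e in self._entries.items()}
            == {f: e.frequency for f, e in other._entries.items()}
        )

    def entry(self, form: Sequence[str]) -> LexicalEntry:
        return self._entries[tuple(form)]

    def frequency(self, form: Sequence[str]) -> float:
        return self._entries[tuple(form)].frequency

    @property
    def forms(self) -> list[Form]:
        return list(self._entries)

    @property
    def total_frequency(self) -> float:
        return sum(e.frequency for e in self._entries.values())

    @property
    def max_length(self) -> int:
        return max((len(f) for f in self._entries), default=0)

    def with_entries(self, new: Iterable[LexicalEntry]) -> "Lexicon":
        """A copy with ``new`` entries appended (original unmodified)."""
        return Lexicon(list(self) + list(new), self.inventory)

    def sorted(self) -> "Lexicon":
        entries = sorted(self, key=lambda e: e.form)
        return Lexicon(entries, self.inventory)


def triple_deviation_point(
    source: Sequence[str], novel: Sequence[str], baseline: Sequence[str]
) -> int:
    """Length of the longest common prefix of the three sequences.

    Symmetric under permutation of its arguments.  Raises ``ValueError`` if
    any sequence is empty or if the common prefix exhausts one full sequence
    (no divergence point exists).
    """
    seqs = [tuple(source), tuple(novel), tuple(baseline)]
    if any(len(s) == 0 for s in seqs):
        raise ValueError("all three sequences must be non-empty")
    dp = 0
    limit = min(len(s) for s in seqs)
    while dp < limit and seqs[0][dp] == seqs[1][dp] == seqs[2][dp]:
        dp += 1
    if dp == limit:
        raise ValueError(
            "common prefix equals one full sequence; no divergence point"
        )
    return dp


def uniqueness_point(word: Sequence[str], lex: Lexicon) -> int | None:
    """Earliest position at which ``word`` is a prefix of no other entry.

    Returns the smallest ``n`` such that ``word[:n]`` is not a prefix of any
    other lexicon entry, or ``None`` if even the full word remains a prefix
    of (or identical to) another entry.
    """
    w = tuple(word)
    if len(w) == 0:
        raise ValueError("word must be non-empty")
    others = [f for f in lex.forms if f != w]
    for n in range(1, len(w) + 1):
        prefix = w[:n]
        if not any(f[:n] == prefix for f in others):
            return n
    return None


@dataclass(frozen=True)
class ItemTriple:
    """Source word plus novel/baseline nonwords sharing a prefix up to a DP.

    ``dp`` is the 1-based count of shared pre-DP phonemes; the three forms
    must pairwise differ at position ``dp + 1``.  Which of the two nonwords
    is "novel" (trained) is swapped under counterbalancing; the field names
    record the default assignment.
    """

    source: Form
    novel: Form
    baseline: Form
    dp: int = -1  # computed when negative

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", tuple(self.source))
        object.__setattr__(self, "novel", tuple(self.novel))
        object.__setattr__(self, "baseline", tuple(self.baseline))
        dp = triple_deviation_point(self.source, self.novel, self.baseline)
        if self.dp < 0:
            object.__setattr__(self, "dp", dp)
        elif self.dp != dp:
            raise ValueError(f"stated dp {self.dp} != computed dp {dp}")
        i = self.dp  # 0-based index of position dp+1
        trio = (self.source[i], self.novel[i], self.baseline[i])
        if len(set(trio)) != 3:
            raise ValueError(
                f"forms must pairwise differ at position dp+1; got {trio}"
            )

    def swapped(self) -> "ItemTriple":
        """The counterbalanced triple (nonword roles exchanged)."""
        return ItemTriple(self.source, self.baseline, self.novel)

    def check_against(self, lex: Lexicon) -> None:
        """Validate the lexicon-dependent invariants for a pre-training lexicon."""
        if self.source not in lex:
            raise ValueError(f"source {' '.join(self.source)} not in lexicon")
        for name in ("novel", "baseline"):
            form = getattr(self, name)
            if form in lex:
                raise ValueError(
                    f"{name} form {' '.join(form)} already present in lexicon"
                )


def train_lexicon(
    lex: Lexicon,
    triples: Sequence[ItemTriple],
    assignment: str | Sequence[str] | Mapping[ItemTriple, str] = "novel",
) -> Lexicon:
    """Add each triple's assigned nonword to the lexicon at its source frequency.

    ``assignment`` selects which nonword field ("novel" or "baseline") is the
    trained item, either globally (a single string), per triple (a sequence
    aligned with ``triples``), or as a mapping.  Returns a new lexicon; the
    input is unmodified.
    """
    if isinstance(assignment, str):
        roles = [assignment] * len(triples)
    elif isinstance(assignment, Mapping):
        roles = [assignment[t] for t in triples]
    else:
        roles = list(assignment)
        if len(roles) != len(triples):
            raise ValueError("assignment length must match number of triples")
    new_entries = []
    seen: set[Form] = set()
    for t, role in zip(triples, roles):
        if role not in ("novel", "baseline"):
            raise ValueError(f"assignment must be 'novel' or 'baseline', got {role!r}")
        if t.source not in lex:
            raise ValueError(f"source {' '.join(t.source)} not in lexicon")
        form = getattr(t, role)
        if form in lex or form in seen:
            raise ValueError(
                f"trained form {' '.join(form)} already exists in lexicon"
            )
        seen.add(form)
        new_entries.append(LexicalEntry(form, lex.frequency(t.source)))
    return lex.with_entries(new_entries)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------
#
# TSV dialect: one entry per line, `orthography <TAB> space-separated
# phonemes <TAB> frequency`; lines starting with `#` and blank lines are
# ignored.  "trace" dialect: the plain-text lexicon format of the public
# C/Java interactive-activation distributions — whitespace-separated phoneme
# string (one character per phoneme) and optional frequency.


def _parse_frequency(text: str, path: str, lineno: int) -> float:
    try:
        freq = float(text)
    except ValueError:
        raise LexiconFormatError(
            f"{path}:{lineno}: frequency is not a number: {text!r}"
        ) from None
    if not math.isfinite(freq) or freq < 0:
        raise LexiconFormatError(
            f"{path}:{lineno}: frequency must be finite and >= 0, got {text}"
        )
    return freq


def read_lexicon(
    path: str | Path,
    dialect: str = "tsv",
    inventory: PhonemeInventory | None = None,
) -> Lexicon:
    """Read a lexicon file.

    If ``inventory`` is given, any symbol outside it is an error naming the
    symbol; otherwise the inventory is inferred from the file (sorted order,
    so that write/read round-trips are the identity).
    """
    path = Path(path)
    entries: list[LexicalEntry] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if dialect == "tsv":
                parts = line.split("\t")
                if len(parts) != 3:
                    raise LexiconFormatError(
                        f"{path}:{lineno}: expected 3 tab-separated fields, "
                        f"got {len(parts)}"
                    )
                orth, phon, freq_s = parts
                form = tuple(phon.split())
                if not form:
                    raise LexiconFormatError(f"{path}:{lineno}: empty phoneme field")
                freq = _parse_frequency(freq_s, str(path), lineno)
                entries.append(LexicalEntry(form, freq, orth))
            elif dialect == "trace":
                parts = line.split()
                if len(parts) not in (1, 2):
                    raise LexiconFormatError(
                        f"{path}:{lineno}: expected `phonemes [frequency]`, "
                        f"got {len(parts)} fields"
                    )
                form = tuple(parts[0])  # one character per phoneme
                freq = (
                    _parse_frequency(parts[1], str(path), lineno)
                    if len(parts) == 2
                    else 1.0
                )
                entries.append(LexicalEntry(form, freq, parts[0]))
            else:
                raise ValueError(f"unknown dialect: {dialect!r}")
    if inventory is None:
        symbols = sorted({p for e in entries for p in e.form})
        inventory = PhonemeInventory(tuple(symbols))
    else:
        for e in entries:
            for p in e.form:
                if p not in inventory:
                    raise LexiconFormatError(f"unknown phoneme symbol: {p!r}")
    return Lexicon(entries, inventory)


def write_lexicon(lex: Lexicon, path: str | Path) -> None:
    """Write the TSV dialect, entries sorted by form (normalized order)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for e in sorted(lex, key=lambda e: e.form):
            fh.write(f"{e.orth}\t{' '.join(e.form)}\t{e.frequency!r}\n")


def read_triples(path: str | Path, lex: Lexicon | None = None) -> list[ItemTriple]:
    """Read an item-triples TSV.

    Columns: ``source_orth <TAB> source_phon <TAB> nonwordA_phon <TAB>
    nonwordB_phon`` with space-separated phonemes; the DP is computed, not
    stored.  If ``lex`` is given, each triple is validated against it.
    """
    path = Path(path)
    triples: list[ItemTriple] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise LexiconFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(parts)}"
                )
            _, source_s, a_s, b_s = parts
            try:
                triple = ItemTriple(
                    tuple(source_s.split()), tuple(a_s.split()), tuple(b_s.split())
                )
            except ValueError as exc:
                raise LexiconFormatError(f"{path}:{lineno}: {exc}") from exc
            if lex is not None:
                triple.check_against(lex)
            triples.append(triple)
    return triples


def write_triples(triples: Sequence[ItemTriple], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for t in triples:
            fh.write(
                "".join(t.source)
                + "\t"
                + " ".join(t.source)
                + "\t"
                + " ".join(t.novel)
                + "\t"
                + " ".join(t.baseline)
                + "\n"
            )
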