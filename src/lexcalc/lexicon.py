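"""Corpus lexicon and its collapsed views.

Words sharing a spelling (homographs), a pronunciation (homophones), or
both are treated as a single lexical representation: a collapsed view
groups corpus entries by orthographic, phonological, or phonographic key
and sums their frequencies.  The phonological key is the phoneme-token
sequence with stress stripped, so pronunciations differing only in stress
placement collapse together; the phonographic key is the
(spelling, phoneme-sequence) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .io_formats import CorpusEntry, InventorySpec
from .phonetics import PhonemeTokenization, tokenize

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "LexicalUnit",
    "CollapsedView",
    "build_lexicon",
    "collapse",
]

KEY_KINDS = ("orthographic", "phonological", "phonographic")


@dataclass(frozen=True)
class LexiconEntry:
    """A corpus entry with its pronunciation tokenized once, eagerly."""

    orthography: str
    pronunciation: Optional[str]
    frequency: float
    tokenization: Optional[PhonemeTokenization]


@dataclass(frozen=True)
class Lexicon:
    """Validated corpus entries in file order."""

    entries: tuple[LexiconEntry, ...]
    with_pronunciation: bool
    inventory: Optional[InventorySpec]


@dataclass(frozen=True)
class LexicalUnit:
    """One collapsed representation.

    ``key`` is the grouping key as a symbol sequence — a letter tuple, a
    phoneme-token tuple, or the pair of both.  ``display_label`` joins the
    distinct member spellings with "/" in corpus order (e.g. "mail/male").
    """

    key: tuple
    members: tuple[LexiconEntry, ...]
    combined_frequency: float
    display_label: str

    @property
    def pronunciation_label(self) -> Optional[str]:
        """The unit's stress-stripped pronunciation string, if it has one."""
        if not self.members or self.members[0].tokenization is None:
            return None
        return "".join(self.members[0].tokenization.tokens)


@dataclass(frozen=True)
class CollapsedView:
    """All units of one key kind, ordered by first appearance in the corpus."""

    key_kind: str
    units: tuple[LexicalUnit, ...]


def build_lexicon(
    entries: Sequence[CorpusEntry],
    inventory: Optional[InventorySpec] = None,
    with_pronunciation: bool = False,
) -> Lexicon:
    """Tokenize every pronunciation and freeze the corpus.

    An untokenizable pronunciation aborts the build, naming the offending
    string.
    """
    built = []
    for e in entries:
        tok = None
        if with_pronunciation and e.pronunciation is not None:
            if inventory is None:
                raise ValueError("an inventory is required to tokenize pronunciations")
            tok = tokenize(e.pronunciation, inventory)
        built.append(LexiconEntry(e.orthography, e.pronunciation, e.frequency, tok))
    return Lexicon(tuple(built), with_pronunciation, inventory)


def entry_key(entry: LexiconEntry, key_kind: str) -> tuple:
    """Grouping key of one entry under a view kind."""
    if key_kind == "orthographic":
        return tuple(entry.orthography)
    if key_kind == "phonological":
        return entry.tokenization.tokens
    if key_kind == "phonographic":
        return (tuple(entry.orthography), entry.tokenization.tokens)
    raise ValueError(f"unknown key kind {key_kind!r}")


def collapse(lex: Lexicon, key_kind: str) -> CollapsedView:
    """Group entries by key, summing frequencies.

    Identical duplicate rows also collapse.  Units keep the corpus order of
    their first member; collapsing is therefore order-stable but the set of
    units and their frequencies are independent of row order.
    """
    if key_kind not in KEY_KINDS:
        raise ValueError(f"unknown key kind {key_kind!r}")
    if key_kind != "orthographic" and not lex.with_pronunciation:
        raise ValueError(f"{key_kind} view requires pronunciations")
    groups: dict[tuple, list[LexiconEntry]] = {}
    for entry in lex.entries:
        groups.setdefault(entry_key(entry, key_kind), []).append(entry)
    units = []
    for key, members in groups.items():
        spellings: dict[str, None] = {}
        for m in members:
            spellings.setdefault(m.orthography)
        units.append(
            LexicalUnit(
                key=key,
                members=tuple(members),
                combined_frequency=sum(m.frequency for m in members),
                display_label="/".join(spellings),
            )
        )
    return CollapsedView(key_kind, tuple(units))
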