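"""Phoneme tokenization and the surface quantities derived from it.

A pronunciation string is segmented into inventory symbols by
deterministic left-to-right longest-match with backtracking: at each
position the candidate symbols (consonants, vowels, and the stress mark)
are tried from longest to shortest, and the search backtracks out of dead
ends, so a segmentation is found whenever one exists.  Ties cannot arise
because inventory symbols are distinct strings.

Stress marks are recorded as positions (the number of phoneme tokens
preceding the mark) and never appear among the tokens, so the token
sequence of /ˈpeɪl/ equals that of /peɪl/ — stress never participates in
phoneme-level metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import TokenizationError, ValidationError
from .io_formats import InventorySpec

__all__ = [
    "PhonemeTokenization",
    "tokenize",
    "reconstruct",
    "count_phonemes",
    "count_syllables",
    "stress_code",
]


@dataclass(frozen=True)
class PhonemeTokenization:
    """A segmented pronunciation.

    ``tokens`` are the phoneme symbols in order; ``stress_positions`` gives,
    for each stress mark in the original string, how many phoneme tokens
    precede it.  Re-inserting the marks at those positions and concatenating
    reproduces the input exactly (see :func:`reconstruct`).
    """

    tokens: tuple[str, ...]
    stress_positions: tuple[int, ...] = ()


def tokenize(pronunciation: str, inventory: InventorySpec) -> PhonemeTokenization:
    """Segment ``pronunciation`` into inventory symbols.

    Longest-match with backtracking over consonants ∪ vowels ∪ {stress
    mark}.  Raises :class:`TokenizationError` (naming the offending string)
    when no complete segmentation exists.
    """
    candidates = sorted(inventory.symbols, key=len, reverse=True)
    stress = inventory.stress_mark
    if stress is not None:
        candidates = sorted(candidates + [stress], key=len, reverse=True)
    n = len(pronunciation)
    dead: set[int] = set()  # suffix start offsets proven unsegmentable

    tokens: list[str] = []
    stress_positions: list[int] = []

    def walk(pos: int) -> bool:
        if pos == n:
            return True
        if pos in dead:
            return False
        for sym in candidates:
            if pronunciation.startswith(sym, pos):
                is_stress = stress is not None and sym == stress
                if is_stress:
                    stress_positions.append(len(tokens))
                else:
                    tokens.append(sym)
                if walk(pos + len(sym)):
                    return True
                if is_stress:
                    stress_positions.pop()
                else:
                    tokens.pop()
        dead.add(pos)
        return False

    if not pronunciation or not walk(0):
        raise TokenizationError(pronunciation)
    return PhonemeTokenization(tuple(tokens), tuple(stress_positions))


def reconstruct(tok: PhonemeTokenization, inventory: InventorySpec) -> str:
    """Inverse of :func:`tokenize`: re-insert stress marks and concatenate."""
    parts: list[str] = []
    marks = list(tok.stress_positions)
    for i, token in enumerate(tok.tokens):
        while marks and marks[0] == i:
            parts.append(inventory.stress_mark or "")
            marks.pop(0)
        parts.append(token)
    parts.extend((inventory.stress_mark or "") for _ in marks)
    return "".join(parts)


def count_phonemes(tok: PhonemeTokenization) -> int:
    """Number of phonemes: stress marks excluded, a diphthong counts once."""
    return len(tok.tokens)


def count_syllables(tok: PhonemeTokenization, inventory: InventorySpec) -> int:
    """Number of syllables, counted as the number of vowel tokens."""
    vowels = set(inventory.vowels)
    return sum(1 for t in tok.tokens if t in vowels)


def stress_code(tok: PhonemeTokenization, inventory: InventorySpec):
    """1-based index of the primary-stressed syllable, or ``None``.

    The mark is read as preceding its syllable (IPA convention): the code is
    one more than the number of vowel tokens before the first mark.  ``None``
    when the pronunciation carries no mark; systems whose users place the
    mark after the syllable still tokenize, but codes follow this
    preceding-mark convention.
    """
    if inventory.stress_mark is None:
        raise ValidationError("Please specify a stress mark in the phonetic system.")
    if not tok.stress_positions:
        return None
    first = tok.stress_positions[0]
    vowels = set(inventory.vowels)
    return sum(1 for t in tok.tokens[:first] if t in vowels) + 1
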