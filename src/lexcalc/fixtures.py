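"""Packaged toy corpora and a seeded synthetic corpus generator.

Two small corpora ship with the package, in the same headerless CSV format
the tool consumes:

* F1 — nine orthography-only entries around "cat" (cat, hat, can, bat, rat,
  cap, cot, at, cats) with small integer frequencies; handy for worked
  neighborhood examples.
* F2 — six word/IPA pairs (sail, mail, male, pail, pale, tale, all /‑eɪl/)
  exercising homophone collapsing; the frequencies are fixture constants
  chosen here, not drawn from any published norm.

The generator produces corpora of distinct random spellings with Zipf-like
frequencies and, optionally, pronunciations derived by a per-letter
grapheme-to-phoneme map (which guarantees tokenizability by construction).
It is deterministic under its seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .io_formats import CorpusEntry, read_corpus_file

__all__ = ["GeneratorParams", "fixture_F1", "fixture_F2", "generate_corpus"]


def _packaged(name: str, with_pronunciation: bool) -> list[CorpusEntry]:
    ref = resources.files("lexcalc").joinpath(f"data/fixtures/{name}")
    with resources.as_file(ref) as p:
        return read_corpus_file(p, with_pronunciation=with_pronunciation)


def fixture_F1() -> list[CorpusEntry]:
    """The 9-entry orthography-only toy corpus."""
    return _packaged("f1.csv", with_pronunciation=False)


def fixture_F2() -> list[CorpusEntry]:
    """The 6-entry homophone toy corpus (spelling, IPA, frequency)."""
    return _packaged("f2.csv", with_pronunciation=True)


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic corpus generator.

    ``zipf_exponent`` shapes the rank-frequency curve (frequency of the
    r-th word ∝ r^-s); 1.0 approximates natural-language token
    distributions.  ``grapheme_to_phoneme`` maps single letters to phoneme
    symbols; when present every entry gets a pronunciation.  ``stress_mark``
    (if set, and pronunciations are generated) is prepended to each
    pronunciation, placing primary stress on the first syllable.
    """

    seed: int
    n_words: int
    alphabet: tuple[str, ...] = tuple("abcdefghij")
    length_range: tuple[int, int] = (2, 7)
    zipf_exponent: float = 1.0
    grapheme_to_phoneme: Optional[dict[str, str]] = None
    stress_mark: Optional[str] = None


def generate_corpus(params: GeneratorParams) -> list[CorpusEntry]:
    """Generate ``n_words`` distinct spellings with Zipf-like frequencies."""
    rng = random.Random(params.seed)
    lo, hi = params.length_range
    spellings: dict[str, None] = {}
    attempts = 0
    while len(spellings) < params.n_words:
        attempts += 1
        if attempts > 1000 * params.n_words + 1000:
            raise ValueError(
                "alphabet/length range too small for the requested corpus size"
            )
        word = "".join(
            rng.choice(params.alphabet) for _ in range(rng.randint(lo, hi))
        )
        spellings.setdefault(word)
    entries = []
    for rank, word in enumerate(spellings, start=1):
        freq = round(1000.0 / rank**params.zipf_exponent, 3)
        freq = max(freq, 0.001)  # strictly positive after rounding
        pron = None
        if params.grapheme_to_phoneme is not None:
            pron = "".join(params.grapheme_to_phoneme[ch] for ch in word)
            if params.stress_mark is not None:
                pron = params.stress_mark + pron
        entries.append(CorpusEntry(word, pron, freq))
    return entries
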