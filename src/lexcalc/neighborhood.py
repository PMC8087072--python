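"""Sequence-generic neighborhood machinery.

Everything here operates on abstract symbol sequences (tuples), so one
implementation serves both the orthographic metrics (letter tuples) and the
phonological metrics (phoneme-token tuples, where a diphthong is a single
symbol).  Neighbor semantics follow the classical definitions: a neighbor
differs by exactly one substitution ("substitutions only"), or is at unit
Levenshtein distance ("substitutions, additions, and deletions").  The
target's own representation — any unit with an identical key — is always
excluded, which is how homograph/homophone exclusion falls out of operating
on collapsed views.

Corpora are desk-scale, so plain O(n·L²) scans are used throughout; there
are no indexing structures to get out of sync.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .errors import ValidationError
from .lexicon import CollapsedView, LexicalUnit

__all__ = [
    "EditRegime",
    "NeighborSet",
    "levenshtein",
    "is_neighbor",
    "neighbors",
    "neighborhood_frequency_stats",
    "ld20",
    "spread",
    "uniqueness_point",
    "clustering_coefficient",
    "sample_mean_sd",
]


class EditRegime(str, Enum):
    """Which single edits make two sequences neighbors."""

    SUBSTITUTION_ONLY = "substitution_only"
    SUBSTITUTION_ADDITION_DELETION = "substitution_addition_deletion"


@dataclass(frozen=True)
class NeighborSet:
    """Collapsed units at distance one from a target under a regime."""

    target_key: tuple
    regime: EditRegime
    units: tuple[LexicalUnit, ...]

    def __len__(self) -> int:
        return len(self.units)


def levenshtein(a: Sequence, b: Sequence) -> int:
    """Unit-cost edit distance over whole symbols."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, sa in enumerate(a, start=1):
        cur = [i]
        for j, sb in enumerate(b, start=1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (sa != sb))
            )
        prev = cur
    return prev[-1]


def is_neighbor(a: Sequence, b: Sequence, regime: EditRegime) -> bool:
    """True when ``a`` and ``b`` differ by exactly one permitted edit.

    Identity is distance 0 and never a neighbor.
    """
    if regime is EditRegime.SUBSTITUTION_ONLY:
        if len(a) != len(b):
            return False
        return sum(x != y for x, y in zip(a, b)) == 1
    if abs(len(a) - len(b)) > 1:
        return False
    return levenshtein(a, b) == 1


def neighbors(
    target: Sequence, view: CollapsedView, regime: EditRegime
) -> NeighborSet:
    """All units neighboring ``target``; units with an identical key excluded."""
    key = tuple(target)
    hits = tuple(
        u for u in view.units if u.key != key and is_neighbor(key, u.key, regime)
    )
    return NeighborSet(key, regime, hits)


def sample_mean_sd(values: Sequence[float]):
    """Mean and sample standard deviation (divisor n−1).

    Mean is ``None`` for no values; sd is ``None`` below two values.
    """
    n = len(values)
    if n == 0:
        return None, None
    mean = sum(values) / n
    if n < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def neighborhood_frequency_stats(ns: NeighborSet):
    """Mean and sample sd of the neighbors' combined frequencies."""
    return sample_mean_sd([u.combined_frequency for u in ns.units])


def ld20(target: Sequence, view: CollapsedView, k: int = 20):
    """Mean and sample sd of the edit distances to the ``k`` closest units.

    Units with a key identical to the target are excluded, so homographs /
    homophones never count among the 20.  Only the multiset of the smallest
    ``k`` distances matters; ties at the k-th rank are value-equivalent.
    """
    key = tuple(target)
    distances = sorted(
        levenshtein(key, u.key) for u in view.units if u.key != key
    )
    if len(distances) < k:
        raise ValidationError(
            "The corpus needs at least 20 unique items if OLD-20/PLD-20 "
            "is selected."
        )
    return sample_mean_sd(distances[:k])


def spread(target: Sequence, view: CollapsedView) -> int:
    """Number of target positions where a substitution yields a neighbor."""
    key = tuple(target)
    positions = set()
    for u in view.units:
        if len(u.key) != len(key) or u.key == key:
            continue
        diffs = [i for i, (x, y) in enumerate(zip(key, u.key)) if x != y]
        if len(diffs) == 1:
            positions.add(diffs[0])
    return len(positions)


def uniqueness_point(target: Sequence, view: CollapsedView) -> int:
    """Earliest prefix length at which the target diverges from all others.

    Smallest n ≥ 1 such that the first n symbols are not a prefix of any
    other unit's key.  A target that never diverges — it is a prefix of, or
    identical to, another word — gets length + 1.
    """
    key = tuple(target)
    others = [u.key for u in view.units if u.key != key]
    for n in range(1, len(key) + 1):
        prefix = key[:n]
        if not any(o[:n] == prefix for o in others):
            return n
    return len(key) + 1


def clustering_coefficient(target: Sequence, view: CollapsedView) -> Optional[float]:
    """Fraction of neighbor pairs that are themselves neighbors.

    Neighbors are taken under substitutions, additions, and deletions; with
    k neighbors the coefficient is E / (k·(k−1)/2) where E counts unordered
    neighbor pairs at unit distance from each other.  Undefined for k < 2.
    """
    ns = neighbors(target, view, EditRegime.SUBSTITUTION_ADDITION_DELETION)
    k = len(ns)
    if k < 2:
        return None
    keys = [u.key for u in ns.units]
    edges = sum(
        is_neighbor(keys[i], keys[j], EditRegime.SUBSTITUTION_ADDITION_DELETION)
        for i in range(k)
        for j in range(i + 1, k)
    )
    return edges / (k * (k - 1) / 2)
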