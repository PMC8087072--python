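"""Position-specific bigram/biphone frequency tables.

A table maps (symbol pair, 1-based position of the pair's first symbol) to
the summed combined frequency of all collapsed units containing that pair
at that position.  The same code builds letter-bigram tables from the
orthographic view and biphone tables from the phonological view (a
diphthong token is one symbol, so /seɪl/ has exactly two biphones).

The summed log-frequency metric applies log10(aggregate + 1) to each of the
target's position-specific pair frequencies and sums across pairs; the +1
smoothing makes pairs unseen in the corpus contribute exactly 0 and keeps
the metric defined for nonwords.  An alternative reading — summing
log-transformed per-word frequencies into the table instead — is available
via ``build_table(view, unit_transform=...)`` with ``log_aggregate=False``
at query time, but is not the default.
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence

from .lexicon import CollapsedView

__all__ = ["PositionalNgramTable", "build_table", "sum_log_frequency"]

#: (symbol pair, 1-based position) -> aggregate frequency
PositionalNgramTable = dict[tuple[tuple, int], float]


def build_table(
    view: CollapsedView,
    unit_transform: Optional[Callable[[float], float]] = None,
) -> PositionalNgramTable:
    """Accumulate each unit's combined frequency over its adjacent pairs.

    The target's own corpus unit, if present, contributes like any other:
    exclusion rules apply to neighbor metrics, not to n-gram tables.
    """
    table: PositionalNgramTable = {}
    for unit in view.units:
        seq = unit.key
        weight = unit.combined_frequency
        if unit_transform is not None:
            weight = unit_transform(weight)
        for i in range(len(seq) - 1):
            entry = ((seq[i], seq[i + 1]), i + 1)
            table[entry] = table.get(entry, 0.0) + weight
    return table


def sum_log_frequency(
    target: Sequence,
    table: PositionalNgramTable,
    log_aggregate: bool = True,
) -> float:
    """Sum of log10(pair frequency + 1) over the target's positional pairs.

    Pairs absent from the corpus contribute log10(1) = 0; a length-1 target
    has no pairs and scores 0.  With ``log_aggregate=False`` the raw table
    entries are summed untransformed (for tables built from pre-transformed
    unit frequencies).
    """
    seq = tuple(target)
    total = 0.0
    for i in range(len(seq) - 1):
        aggregate = table.get(((seq[i], seq[i + 1]), i + 1), 0.0)
        total += math.log10(aggregate + 1.0) if log_aggregate else aggregate
    return total
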