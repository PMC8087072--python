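"""Independent naive reference implementations.

Everything here is written for obviousness, not speed, and shares no code
with the package: collapsing via dict-of-lists, Levenshtein via memoized
recursion, neighborhoods via exhaustive pairwise scans, tokenizability via
exhaustive segmentation enumeration.  Tests compare the package's results
against these.
"""

import math
from functools import lru_cache
from statistics import mean, stdev


def collapse_oracle(rows, kind):
    """rows: (spelling, phoneme-tuple-or-None, freq). Returns list of
    (key, label, combined_freq, pron_string) in first-appearance order."""
    groups = {}
    order = []
    for orth, phon, freq in rows:
        if kind == "orthographic":
            key = tuple(orth)
        elif kind == "phonological":
            key = phon
        else:
            key = (tuple(orth), phon)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append((orth, phon, freq))
    out = []
    for key in order:
        members = groups[key]
        label_parts = []
        for orth, _, _ in members:
            if orth not in label_parts:
                label_parts.append(orth)
        pron = members[0][1]
        out.append(
            (
                key,
                "/".join(label_parts),
                sum(f for _, _, f in members),
                "".join(pron) if pron is not None else None,
            )
        )
    return out


@lru_cache(maxsize=None)
def lev_recursive(a, b):
    if not a:
        return len(b)
    if not b:
        return len(a)
    cost = 0 if a[0] == b[0] else 1
    return min(
        lev_recursive(a[1:], b) + 1,
        lev_recursive(a, b[1:]) + 1,
        lev_recursive(a[1:], b[1:]) + cost,
    )


def is_neighbor_oracle(a, b, sad):
    if a == b:
        return False
    if sad:
        return lev_recursive(a, b) == 1
    return len(a) == len(b) and sum(x != y for x, y in zip(a, b)) == 1


def neighbors_oracle(target, units, sad):
    """units: output of collapse_oracle. Keeps unit order."""
    return [u for u in units if is_neighbor_oracle(target, u[0], sad)]


def freq_stats_oracle(neighbor_units):
    freqs = [u[2] for u in neighbor_units]
    m = mean(freqs) if freqs else None
    s = stdev(freqs) if len(freqs) >= 2 else None
    return m, s


def ld20_oracle(target, units, k=20):
    dists = sorted(
        lev_recursive(target, u[0]) for u in units if u[0] != target
    )
    if len(dists) < k:
        return None
    top = dists[:k]
    return mean(top), stdev(top)


def spread_oracle(target, units):
    count = 0
    for i in range(len(target)):
        # some unit differs from the target at position i and nowhere else
        if any(
            len(u[0]) == len(target)
            and u[0] != target
            and [j for j in range(len(target)) if u[0][j] != target[j]] == [i]
            for u in units
        ):
            count += 1
    return count


def uniqueness_oracle(target, units):
    others = [u[0] for u in units if u[0] != target]
    for n in range(1, len(target) + 1):
        if not any(o[:n] == target[:n] for o in others):
            return n
    return len(target) + 1


def clustering_oracle(target, units):
    nbrs = [u[0] for u in neighbors_oracle(target, units, sad=True)]
    k = len(nbrs)
    if k < 2:
        return None
    edges = 0
    for i in range(k):
        for j in range(i + 1, k):
            if lev_recursive(nbrs[i], nbrs[j]) == 1:
                edges += 1
    return edges / (k * (k - 1) / 2)


def bigram_table_oracle(units):
    table = {}
    for key, _, freq, _ in units:
        for i in range(len(key) - 1):
            slot = ((key[i], key[i + 1]), i + 1)
            table[slot] = table.get(slot, 0.0) + freq
    return table


def sum_log_oracle(target, table):
    total = 0.0
    for i in range(len(target) - 1):
        total += math.log10(table.get(((target[i], target[i + 1]), i + 1), 0.0) + 1)
    return total


def segmentable(string, symbols):
    """Exhaustive check: can ``string`` be split into symbols at all?"""
    if string == "":
        return True
    return any(
        string.startswith(s) and segmentable(string[len(s):], symbols)
        for s in symbols
    )
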