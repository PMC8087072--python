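"""Per-target metric assembly.

Dispatches each selected metric to the phonetics / neighborhood / n-gram
machinery and assembles one output row per input record, keyed by the fixed
output column headings.  Orthographic metrics run on the letter sequence
over the orthographic view; phonological metrics on the stress-stripped
phoneme tokens over the phonological view; phonographic metrics over the
phonographic view, where a unit is a neighbor iff its spelling neighbors
the target's spelling AND its pronunciation neighbors the target's
pronunciation (the regime applies to both channels).

Undefined values (e.g. the frequency sd of a single-neighbor word, or the
stress code of an unstressed pronunciation) are rendered as empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ValidationError
from .io_formats import InputRecord, InventorySpec, OutputTable, render_value
from .lexicon import CollapsedView, Lexicon, collapse
from .neighborhood import (
    EditRegime,
    NeighborSet,
    clustering_coefficient,
    is_neighbor,
    ld20,
    neighborhood_frequency_stats,
    neighbors,
    sample_mean_sd,
    spread,
    uniqueness_point,
)
from .phonetics import count_phonemes, count_syllables, stress_code, tokenize
from .positional_ngrams import build_table, sum_log_frequency

__all__ = [
    "MetricSelection",
    "METRIC_HEADINGS",
    "METRIC_CATEGORIES",
    "ALL_METRICS",
    "DEFAULT_METRICS",
    "default_selection",
    "validate_selection",
    "stress_typicality",
    "build_views",
    "compute_row",
    "compute_table",
]

ORTH_ID = "Words (orthographic)"
PHON_ID = "Words (phonological)"

#: metric id -> output column headings, in canonical output order
METRIC_HEADINGS: dict[str, tuple[str, ...]] = {
    "stress_code": ("Stress Code",),
    "stress_typicality": ("Stress Typicality",),
    "length": ("Length",),
    "orthographic_density": (
        "Orthographic Neighbourhood Density",
        "Identity of Orthographic neighbours",
    ),
    "orthographic_frequency": (
        "Orthographic Neighbourhood Frequency (M)",
        "Orthographic Neighbourhood Frequency (SD)",
    ),
    "old20": ("OLD-20 (M)", "OLD-20 (SD)"),
    "orthographic_spread": ("Orthographic Spread",),
    "orthographic_uniqueness_point": ("Orthographic Uniqueness Point",),
    "orthographic_c": ("Orthographic C Coefficient",),
    "sum_bigram_frequency": ("Sum Bigram Frequency",),
    "n_phonemes": ("No. of Phonemes",),
    "n_syllables": ("No. of Syllables",),
    "phonological_density": (
        "Phonological Neighbourhood Density",
        "Identity of Phonological neighbours (O)",
        "Identity of Phonological neighbours (P)",
    ),
    "phonological_frequency": (
        "Phonological Neighbourhood Frequency (M)",
        "Phonological Neighbourhood Frequency (SD)",
    ),
    "pld20": ("PLD-20 (M)", "PLD-20 (SD)"),
    "phonological_spread": ("Phonological Spread",),
    "phonological_uniqueness_point": ("Phonological Uniqueness Point",),
    "phonological_c": ("Phonological C Coefficient",),
    "sum_biphone_frequency": ("Sum Biphone Frequency",),
    "phonographic_density": (
        "Phonographic Neighbourhood Density",
        "Identity of Phonographic neighbours (O)",
        "Identity of Phonographic neighbours (P)",
    ),
    "phonographic_frequency": (
        "Phonographic Neighbourhood Frequency (M)",
        "Phonographic Neighbourhood Frequency (SD)",
    ),
    "phonographic_c": ("Phonographic C Coefficient",),
}

ALL_METRICS: tuple[str, ...] = tuple(METRIC_HEADINGS)

METRIC_CATEGORIES: dict[str, str] = {
    "stress_code": "surface",
    "stress_typicality": "surface",
    "length": "orthographic",
    "orthographic_density": "orthographic",
    "orthographic_frequency": "orthographic",
    "old20": "orthographic",
    "orthographic_spread": "orthographic",
    "orthographic_uniqueness_point": "orthographic",
    "orthographic_c": "orthographic",
    "sum_bigram_frequency": "orthographic",
    "n_phonemes": "phonological",
    "n_syllables": "phonological",
    "phonological_density": "phonological",
    "phonological_frequency": "phonological",
    "pld20": "phonological",
    "phonological_spread": "phonological",
    "phonological_uniqueness_point": "phonological",
    "phonological_c": "phonological",
    "sum_biphone_frequency": "phonological",
    "phonographic_density": "phonographic",
    "phonographic_frequency": "phonographic",
    "phonographic_c": "phonographic",
}

#: the 'Default' set: phoneme/syllable counts, both densities and
#: frequencies (substitutions, additions, and deletions), and both LD-20s
DEFAULT_METRICS: tuple[str, ...] = (
    "orthographic_density",
    "orthographic_frequency",
    "old20",
    "n_phonemes",
    "n_syllables",
    "phonological_density",
    "phonological_frequency",
    "pld20",
)


@dataclass(frozen=True)
class MetricSelection:
    """Which metrics to compute, and the edit regime for density/frequency.

    ``regime`` governs the neighborhood density and frequency families; the
    LD-20, spread, uniqueness-point, and C-coefficient metrics have fixed
    regimes by definition.
    """

    metrics: tuple[str, ...]
    regime: EditRegime = EditRegime.SUBSTITUTION_ADDITION_DELETION

    def __post_init__(self):
        unknown = [m for m in self.metrics if m not in METRIC_HEADINGS]
        if unknown:
            raise ValueError(f"unknown metrics: {', '.join(unknown)}")
        # canonical output order, duplicates dropped
        ordered = tuple(m for m in ALL_METRICS if m in set(self.metrics))
        object.__setattr__(self, "metrics", ordered)

    def categories(self) -> set[str]:
        return {METRIC_CATEGORIES[m] for m in self.metrics}


def default_selection() -> MetricSelection:
    """The 'Default' metric set, under substitutions, additions, deletions."""
    return MetricSelection(DEFAULT_METRICS, EditRegime.SUBSTITUTION_ADDITION_DELETION)


def validate_selection(
    selection: MetricSelection,
    with_pronunciation: bool,
    inventory: Optional[InventorySpec],
) -> None:
    """Check the selection against data availability before any computation."""
    if not selection.metrics:
        raise ValidationError("No metrics have been selected.")
    cats = selection.categories()
    if "phonological" in cats and not with_pronunciation:
        raise ValidationError(
            "Words (phonological) must not be empty for phonological metrics."
        )
    if "phonographic" in cats and not with_pronunciation:
        raise ValidationError(
            "Words (phonological) and Words (orthographic) must not be empty "
            "for phonographic metrics."
        )
    if "surface" in cats:
        if not with_pronunciation:
            raise ValidationError(
                "Words (phonological) must not be empty for surface metrics."
            )
        if inventory is None or inventory.stress_mark is None:
            raise ValidationError(
                "Please specify a stress mark in the phonetic system."
            )


def validate_records(
    records: Sequence[InputRecord], selection: MetricSelection
) -> None:
    """Check that every record carries the fields the selection needs."""
    cats = selection.categories()
    for r in records:
        if "orthographic" in cats and not r.orthography:
            raise ValidationError(
                "Words (orthographic) must not be empty for orthographic metrics."
            )
        if ("phonological" in cats or "surface" in cats) and not r.pronunciation:
            raise ValidationError(
                "Words (phonological) must not be empty for "
                + ("phonological" if "phonological" in cats else "surface")
                + " metrics."
            )
        if "phonographic" in cats and not (r.orthography and r.pronunciation):
            raise ValidationError(
                "Words (phonological) and Words (orthographic) must not be "
                "empty for phonographic metrics."
            )


def stress_typicality(
    target_tok, view: CollapsedView, inventory: InventorySpec
) -> Optional[float]:
    """Proportion of same-syllable-count units sharing the target's stress.

    Type-weighted over collapsed phonological units: the numerator counts
    units with the target's syllable count and stress code, the denominator
    units with that syllable count and any defined stress code.  A unit's
    stress code comes from its first member carrying a stress mark.
    Undefined when the target has no stress code or the denominator is 0.
    """
    target_code = stress_code(target_tok, inventory)
    if target_code is None:
        return None
    target_syll = count_syllables(target_tok, inventory)
    num = den = 0
    for unit in view.units:
        unit_code = None
        for m in unit.members:
            if m.tokenization is not None and m.tokenization.stress_positions:
                unit_code = stress_code(m.tokenization, inventory)
                break
        if unit_code is None:
            continue
        syll = sum(1 for t in unit.key if t in set(inventory.vowels))
        if syll != target_syll:
            continue
        den += 1
        if unit_code == target_code:
            num += 1
    return num / den if den else None


def build_views(lex: Lexicon, selection: MetricSelection) -> dict:
    """Build the collapsed views and n-gram tables the selection needs."""
    views: dict = {}
    cats = selection.categories()
    metrics = set(selection.metrics)
    needs_orth = bool(
        metrics
        & {
            "orthographic_density",
            "orthographic_frequency",
            "old20",
            "orthographic_spread",
            "orthographic_uniqueness_point",
            "orthographic_c",
            "sum_bigram_frequency",
        }
    )
    if needs_orth:
        views["orthographic"] = collapse(lex, "orthographic")
    if ("phonological" in cats and metrics - {"n_phonemes", "n_syllables"}) or (
        "surface" in cats
    ):
        views["phonological"] = collapse(lex, "phonological")
    if "phonographic" in cats:
        views["phonographic"] = collapse(lex, "phonographic")
    if "sum_bigram_frequency" in metrics:
        views["bigram_table"] = build_table(views["orthographic"])
    if "sum_biphone_frequency" in metrics:
        views["biphone_table"] = build_table(views["phonological"])
    return views


def _phonographic_neighbors(
    orth_seq: tuple, phon_seq: tuple, view: CollapsedView, regime: EditRegime
) -> NeighborSet:
    """Units neighboring the target in both channels simultaneously.

    Units sharing the target's spelling (homographs) or pronunciation
    (homophones) are excluded outright, the exact-identity unit a fortiori.
    """
    hits = []
    for u in view.units:
        u_orth, u_phon = u.key
        if u_orth == orth_seq or u_phon == phon_seq:
            continue
        if is_neighbor(orth_seq, u_orth, regime) and is_neighbor(
            phon_seq, u_phon, regime
        ):
            hits.append(u)
    return NeighborSet((orth_seq, phon_seq), regime, tuple(hits))


def _identity_cells(ns: NeighborSet) -> tuple[str, Optional[str]]:
    """Render neighbor identities: spellings and, if available, pronunciations."""
    orth = "; ".join(u.display_label for u in ns.units)
    prons = [u.pronunciation_label for u in ns.units]
    phon = "; ".join(p for p in prons if p is not None) if any(prons) else None
    return orth, phon


def compute_row(
    record: InputRecord,
    lex: Lexicon,
    views: dict,
    selection: MetricSelection,
    inventory: Optional[InventorySpec] = None,
) -> dict:
    """Compute every selected metric for one target.

    Returns a mapping from column heading to a raw value (``None`` for
    undefined).  Nonwords are first-class: every metric is computed against
    the corpus exactly as for real words.
    """
    row: dict = {ORTH_ID: record.orthography}
    if lex.with_pronunciation:
        row[PHON_ID] = record.pronunciation

    orth_seq = tuple(record.orthography)
    tok = None
    phon_seq: tuple = ()
    if record.pronunciation is not None and inventory is not None:
        tok = tokenize(record.pronunciation, inventory)
        phon_seq = tok.tokens

    regime = selection.regime
    for metric in selection.metrics:
        h = METRIC_HEADINGS[metric]
        if metric == "length":
            row[h[0]] = len(orth_seq)
        elif metric == "n_phonemes":
            row[h[0]] = count_phonemes(tok)
        elif metric == "n_syllables":
            row[h[0]] = count_syllables(tok, inventory)
        elif metric == "stress_code":
            row[h[0]] = stress_code(tok, inventory)
        elif metric == "stress_typicality":
            row[h[0]] = stress_typicality(tok, views["phonological"], inventory)
        elif metric in ("orthographic_density", "phonological_density"):
            seq, view = (
                (orth_seq, views["orthographic"])
                if metric.startswith("orth")
                else (phon_seq, views["phonological"])
            )
            ns = neighbors(seq, view, regime)
            orth_cell, phon_cell = _identity_cells(ns)
            row[h[0]] = len(ns)
            row[h[1]] = orth_cell
            if len(h) > 2:
                row[h[2]] = phon_cell
        elif metric in ("orthographic_frequency", "phonological_frequency"):
            seq, view = (
                (orth_seq, views["orthographic"])
                if metric.startswith("orth")
                else (phon_seq, views["phonological"])
            )
            mean, sd = neighborhood_frequency_stats(neighbors(seq, view, regime))
            row[h[0]], row[h[1]] = mean, sd
        elif metric in ("old20", "pld20"):
            seq, view = (
                (orth_seq, views["orthographic"])
                if metric == "old20"
                else (phon_seq, views["phonological"])
            )
            mean, sd = ld20(seq, view)
            row[h[0]], row[h[1]] = mean, sd
        elif metric in ("orthographic_spread", "phonological_spread"):
            seq, view = (
                (orth_seq, views["orthographic"])
                if metric.startswith("orth")
                else (phon_seq, views["phonological"])
            )
            row[h[0]] = spread(seq, view)
        elif metric in (
            "orthographic_uniqueness_point",
            "phonological_uniqueness_point",
        ):
            seq, view = (
                (orth_seq, views["orthographic"])
                if metric.startswith("orth")
                else (phon_seq, views["phonological"])
            )
            row[h[0]] = uniqueness_point(seq, view)
        elif metric in ("orthographic_c", "phonological_c"):
            seq, view = (
                (orth_seq, views["orthographic"])
                if metric.startswith("orth")
                else (phon_seq, views["phonological"])
            )
            row[h[0]] = clustering_coefficient(seq, view)
        elif metric == "sum_bigram_frequency":
            row[h[0]] = sum_log_frequency(orth_seq, views["bigram_table"])
        elif metric == "sum_biphone_frequency":
            row[h[0]] = sum_log_frequency(phon_seq, views["biphone_table"])
        elif metric == "phonographic_density":
            ns = _phonographic_neighbors(
                orth_seq, phon_seq, views["phonographic"], regime
            )
            row[h[0]] = len(ns)
            orth_cell = "; ".join(u.display_label for u in ns.units)
            phon_cell = "; ".join(
                u.pronunciation_label or "" for u in ns.units
            )
            row[h[1]], row[h[2]] = orth_cell, phon_cell
        elif metric == "phonographic_frequency":
            ns = _phonographic_neighbors(
                orth_seq, phon_seq, views["phonographic"], regime
            )
            mean, sd = sample_mean_sd([u.combined_frequency for u in ns.units])
            row[h[0]], row[h[1]] = mean, sd
        elif metric == "phonographic_c":
            sad = EditRegime.SUBSTITUTION_ADDITION_DELETION
            ns = _phonographic_neighbors(
                orth_seq, phon_seq, views["phonographic"], sad
            )
            k = len(ns)
            if k < 2:
                row[h[0]] = None
            else:
                edges = 0
                for i in range(k):
                    for j in range(i + 1, k):
                        oi, pi = ns.units[i].key
                        oj, pj = ns.units[j].key
                        if is_neighbor(oi, oj, sad) and is_neighbor(pi, pj, sad):
                            edges += 1
                row[h[0]] = edges / (k * (k - 1) / 2)
    return row


def compute_table(
    records: Sequence[InputRecord],
    lex: Lexicon,
    selection: MetricSelection,
    inventory: Optional[InventorySpec] = None,
    progress=None,
) -> OutputTable:
    """Compute all rows, in input order, and render them for writing.

    ``progress`` is an optional callback ``(done, total)`` invoked after
    each row.
    """
    validate_selection(selection, lex.with_pronunciation, inventory)
    validate_records(records, selection)
    views = build_views(lex, selection)
    headings = [ORTH_ID] + ([PHON_ID] if lex.with_pronunciation else [])
    for m in selection.metrics:
        headings.extend(METRIC_HEADINGS[m])
    table = OutputTable(column_headings=headings)
    for i, record in enumerate(records, start=1):
        raw = compute_row(record, lex, views, selection, inventory)
        table.rows.append({k: render_value(v) for k, v in raw.items()})
        if progress is not None:
            progress(i, len(records))
    return table
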