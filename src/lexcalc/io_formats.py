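"""Reading and writing the four CSV file kinds.

All files are headerless CSV UTF-8 (comma delimited): row 1 is data and is
never skipped.  Three kinds are read — the input file (targets), the corpus
file (lexicon + frequencies), and the phonetic-system file (consonant /
vowel / stress-mark columns) — and one is written (the output table).

Cells are stripped of leading/trailing whitespace; a whitespace-only cell
counts as empty.  Comparisons are case-sensitive and no Unicode
normalization is applied beyond UTF-8 decoding, so IPA symbols written with
combining diacritics (e.g. "ɑ̃") must appear byte-identically in the corpus
and the phonetic system.  Files are decoded as UTF-8 with an optional BOM
(the "CSV UTF-8" flavour spreadsheet programs produce).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .errors import ValidationError

__all__ = [
    "InputRecord",
    "CorpusEntry",
    "InventorySpec",
    "OutputTable",
    "BUILTIN_INVENTORIES",
    "read_input_file",
    "read_corpus_file",
    "read_phonetic_system_file",
    "load_builtin_inventory",
    "write_output",
    "write_corpus_file",
    "render_value",
]

#: frequency cells: at least one digit, at most one '.', no sign, no exponent
_FREQUENCY_RE = re.compile(r"^(?:\d+\.?\d*|\.\d+)$")

#: builtin phonetic-system identifiers (language + transcription scheme)
BUILTIN_INVENTORIES = (
    "en_US-IPA",
    "en_US-Klattese",
    "en_US-SAMPA",
    "en_UK-IPA",
    "en_UK-SAMPA",
    "fr-IPA",
    "fr-SAMPA",
    "es-IPA",
    "es-SAMPA",
    "nl-IPA",
    "nl-SAMPA",
    "de-IPA",
    "de-SAMPA",
)


@dataclass(frozen=True)
class InputRecord:
    """One target item: a spelling and, optionally, its pronunciation."""

    orthography: str
    pronunciation: Optional[str] = None


@dataclass(frozen=True)
class CorpusEntry:
    """One corpus row: spelling, optional pronunciation, word frequency.

    Frequency units are whatever the corpus uses (raw counts, counts per
    million, ...); the metrics only ever sum and average them.
    """

    orthography: str
    pronunciation: Optional[str]
    frequency: float


@dataclass(frozen=True)
class InventorySpec:
    """A phonetic system: consonant and vowel symbol sets plus a stress mark.

    Symbols may span several characters; a diphthong listed as one entry is
    tokenized as a single vowel.  ``stress_mark`` is the primary-stress
    symbol or ``None`` when the system defines none (surface metrics then
    refuse to run).
    """

    consonants: tuple[str, ...]
    vowels: tuple[str, ...]
    stress_mark: Optional[str] = None

    def __post_init__(self) -> None:
        overlap = set(self.consonants) & set(self.vowels)
        if overlap or "" in self.consonants or "" in self.vowels:
            raise ValidationError("The phonetic system file format is incorrect.")
        if self.stress_mark is not None and (
            self.stress_mark == "" or self.stress_mark in self.symbols
        ):
            raise ValidationError("The phonetic system file format is incorrect.")

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self.consonants) | frozenset(self.vowels)


@dataclass
class OutputTable:
    """Ordered output columns and one row of rendered cells per target."""

    column_headings: list[str]
    rows: list[dict[str, str]] = field(default_factory=list)


def _read_rows(path, kind: str) -> list[list[str]]:
    """Read a headerless CSV as a list of stripped-cell rows.

    ``kind`` ("input" / "corpus" / "phonetic system") selects the wording of
    the diagnostics.  Rows that are entirely empty (blank trailing lines)
    are dropped; partially empty rows are kept for the caller to validate.
    """
    if path is None or str(path) == "":
        article = "an" if kind == "input" else "a"
        raise ValidationError(
            f"No {kind} file is selected. Please select {article} {kind} file."
        )
    p = Path(path)
    if not p.exists():
        if kind == "input":
            raise ValidationError(
                "The specified input file cannot be found in the directory."
            )
        raise ValidationError(
            f"The specified {kind} file was not found in the directory."
        )
    try:
        with open(p, newline="", encoding="utf-8-sig") as fh:
            rows = [[cell.strip() for cell in row] for row in csv.reader(fh)]
    except UnicodeDecodeError:
        raise ValidationError(
            f"Unable to read {kind} file. "
            "Please check that it is saved in CSV format."
        ) from None
    except (OSError, csv.Error):
        raise ValidationError(
            f"Unable to read {kind} file. Please close the file if it is open."
        ) from None
    return [row for row in rows if any(cell != "" for cell in row)]


def read_input_file(path, with_pronunciation: bool = False) -> list[InputRecord]:
    """Read target items, in file order.

    Column 1 is the orthographic form; column 2, when the run is configured
    with pronunciations, the pronunciation.  Any required cell that is
    missing or empty aborts the read.
    """
    records = []
    for row in _read_rows(path, "input"):
        orth = row[0] if len(row) > 0 else ""
        pron = row[1] if len(row) > 1 else ""
        if orth == "" or (with_pronunciation and pron == ""):
            raise ValidationError(
                "There are empty cells in the input. Please check the input file."
            )
        records.append(
            InputRecord(orth, pron if with_pronunciation else None)
        )
    return records


def read_corpus_file(path, with_pronunciation: bool = False) -> list[CorpusEntry]:
    """Read corpus rows, in file order.

    Column 1 is the spelling and the final column the word frequency; with
    pronunciations the file must have exactly 3 columns (spelling,
    pronunciation, frequency).  Frequencies must consist of digits and at
    most one decimal point — no signs, no exponent notation.
    """
    entries = []
    for row in _read_rows(path, "corpus"):
        if with_pronunciation:
            if len(row) != 3:
                raise ValidationError(
                    "The corpus file format is incorrect. "
                    "Please ensure that there are 3 columns."
                )
            orth, pron, freq_cell = row
        else:
            if len(row) < 2:
                raise ValidationError(
                    "There are empty cells in the corpus. "
                    "Please check the corpus file."
                )
            orth, pron, freq_cell = row[0], None, row[-1]
        if orth == "" or freq_cell == "" or (with_pronunciation and pron == ""):
            raise ValidationError(
                "There are empty cells in the corpus. Please check the corpus file."
            )
        if not _FREQUENCY_RE.match(freq_cell):
            raise ValidationError(
                "Please ensure that only numbers are in the frequency column "
                "of the corpus file."
            )
        entries.append(CorpusEntry(orth, pron, float(freq_cell)))
    return entries


def read_phonetic_system_file(path) -> InventorySpec:
    """Read a user-specified phonetic system.

    Column 1 lists consonants, column 2 vowels, column 3 the primary-stress
    mark (first nonempty cell).  Columns may be ragged — empty cells within
    a column are ignored.  Multi-character cells are kept whole, so a
    diphthong listed as one entry becomes a single vowel symbol.
    """
    rows = _read_rows(path, "phonetic system")
    if not rows or max(len(row) for row in rows) < 2:
        raise ValidationError("The phonetic system file format is incorrect.")

    def column(i: int) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for row in rows:
            if i < len(row) and row[i] != "":
                seen.setdefault(row[i])
        return tuple(seen)

    stress_cells = column(2)
    return InventorySpec(
        consonants=column(0),
        vowels=column(1),
        stress_mark=stress_cells[0] if stress_cells else None,
    )


def load_builtin_inventory(system_id: str) -> InventorySpec:
    """Load one of the packaged phonetic systems by identifier.

    Identifiers combine a language tag and a transcription scheme, e.g.
    ``en_US-IPA`` or ``de-SAMPA``; Klattese exists only for English (US).
    """
    if system_id not in BUILTIN_INVENTORIES:
        raise ValueError(
            f"Unknown phonetic system {system_id!r}. "
            f"Valid identifiers: {', '.join(BUILTIN_INVENTORIES)}."
        )
    ref = resources.files("lexcalc").joinpath(f"data/{system_id}.csv")
    with resources.as_file(ref) as p:
        return read_phonetic_system_file(p)


def render_value(value) -> str:
    """Render one output cell: '' for undefined, full precision for floats."""
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_output(path, table: OutputTable) -> None:
    """Write the output table as headed CSV UTF-8 (with BOM).

    Undefined metric values become empty cells.  Multi-unit neighbor lists
    are already joined with "; " and collapsed homophone spellings with "/"
    upstream, so no cell ever contains an unescaped field delimiter.
    """
    try:
        fh = open(path, "w", newline="", encoding="utf-8-sig")
    except OSError:
        raise ValidationError(
            f"The file {Path(path).name} is open. Please close it."
        ) from None
    with fh:
        writer = csv.writer(fh)
        writer.writerow(table.column_headings)
        for row in table.rows:
            writer.writerow([row.get(h, "") for h in table.column_headings])


def write_corpus_file(path, entries: Sequence[CorpusEntry]) -> None:
    """Write corpus entries back out in the headerless corpus format."""
    with open(path, "w", newline="", encoding="utf-8-sig") as fh:
        writer = csv.writer(fh)
        for e in entries:
            freq = render_value(e.frequency)
            if e.pronunciation is None:
                writer.writerow([e.orthography, freq])
            else:
                writer.writerow([e.orthography, e.pronunciation, freq])
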