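# Methods

This note records how each quantity is defined, the conventions adopted where
several defensible readings exist, and what the packaged tests do and do not
establish.

## Lexicon model

A corpus is an ordered list of (orthography, optional pronunciation,
frequency) rows. Frequencies are corpus-defined units (counts, counts per
million, ...); the package only sums and averages them, so the unit cancels
out of every proportion and only scales the frequency metrics.

All neighborhood-style metrics operate on **collapsed views** of the corpus:

- *orthographic* key — the spelling (letter sequence);
- *phonological* key — the phoneme-token sequence with stress stripped;
- *phonographic* key — the (spelling, phoneme-sequence) pair.

Rows sharing a key form one **lexical unit** whose frequency is the sum of
its members' frequencies and whose display label joins the distinct member
spellings with "/" in corpus order ("mail/male"). Identical duplicate rows
collapse too. Two consequences follow automatically: homophones or
homographs among a target's neighbors are counted once with summed
frequency, and the target's own homographs/homophones never appear in its
neighborhood, because any unit whose key equals the target's is excluded.
Pronunciations differing only in stress placement share a phonological key
and are therefore homophones for neighborhood purposes; phoneme-level
metrics are defined over phonemes, not prosody. This is a convention, not a
forced choice, and is noted here because corpora with stress-contrastive
pairs (e.g. noun/verb stress alternations) will collapse them.

## Tokenization

Pronunciations are segmented against an inventory (consonants, vowels,
optional stress mark) by left-to-right longest-match **with backtracking**:
at each position candidate symbols are tried longest first, and the search
backtracks out of dead ends, so a segmentation is found whenever one exists
(verified against exhaustive enumeration on small inventories). Matching is
deterministic; ties cannot arise because symbols are distinct strings. A
string with no segmentation aborts the run, naming the string. Multi-entry
cells are never split: a diphthong listed as a single entry is one vowel
token, which is what makes "number of phonemes" and "number of syllables"
(= vowel-token count) well defined for systems with diphthongs.

Stress marks are recorded as positions between tokens and never enter the
token sequence. The stress code reads the mark as *preceding* its syllable
(IPA convention): code = 1 + number of vowel tokens before the first mark.
The built-in IPA systems ship "ˈ", SAMPA systems '"', and Klattese "'" as
editable packaged data; a user system with a trailing-mark convention still
tokenizes, but its codes follow the preceding-mark rule. A pronunciation
without a mark has an undefined stress code (empty output cell). Whether a
stress *pattern string* rather than an index would better serve some users
was an open design point; the 1-based index was chosen as the simplest
faithful encoding.

No Unicode normalization is applied anywhere: comparisons are case-sensitive
and byte-exact after UTF-8 decoding, because normalization would silently
rewrite IPA combining sequences (e.g. "ɑ̃", "l̩"). Corpus and phonetic-system
files must therefore agree on their encoding of composed characters.

## Neighborhood metrics

One sequence-generic engine serves letters and phoneme tokens; the
definitions are word-for-word parallel, so a single implementation is
tested once and reused.

- **Density / frequency** — neighbors are units at Hamming distance 1
  (substitutions only) or Levenshtein distance 1 (substitutions, additions,
  deletions). Frequency statistics are the mean and *sample* standard
  deviation (divisor n−1, used consistently everywhere) of the neighbors'
  combined frequencies; the mean is undefined with 0 neighbors, the SD
  below 2.
- **OLD-20 / PLD-20** — mean ± sample SD of the 20 smallest distances from
  the target to non-identical units. Ties at the 20th rank are resolved by
  the value multiset, which is the only observable choice. Fewer than 20
  eligible units is a validation error, raised before any output is
  written.
- **Spread** — number of positions at which some substitution produces a
  unit.
- **Uniqueness point** — smallest n such that the target's first n symbols
  are a prefix of no other unit. A target that is a prefix of (or equal to)
  another word never diverges; it is assigned length+1, the first position
  "past the end". The convention is arbitrary but monotone: the value never
  decreases as the corpus grows.
- **Clustering coefficient** — with k ≥ 2 neighbors under
  substitutions/additions/deletions, E / (k(k−1)/2) where E counts neighbor
  pairs at unit distance from each other; undefined for k < 2.
- **Phonographic neighbors** — the conjunction of the two channel tests: a
  unit neighbors the target iff its spelling neighbors the target's spelling
  and its pronunciation neighbors the target's pronunciation, with no
  requirement that the two edits be "the same" edit or at aligned positions.
  Units sharing the target's spelling or pronunciation are excluded
  outright (they are homographs/homophones). The phonographic C coefficient
  applies the substitutions/additions/deletions test in both channels.

## Positional bigram/biphone frequencies

The table maps (adjacent symbol pair, 1-based position of the pair's first
symbol) to the summed combined frequency of units containing that pair at
that position; there is no word-boundary padding. The metric is
Σ log₁₀(aggregate + 1) over the target's pairs. The "+1 inside the log of
the aggregate" reading is a genuine design decision: summing per-word log
frequencies instead is equally defensible and remains available
(`build_table(view, unit_transform=...)` + `sum_log_frequency(...,
log_aggregate=False)`), but the aggregate-then-log form is the default
because it makes unseen pairs contribute exactly 0 and stays finite for
nonwords. The target's own corpus entry, if present, contributes to the
table; exclusion rules are a neighbor-metric concept and are not applied
here.

## Stress typicality

Type-weighted over collapsed phonological units: numerator = units with the
target's syllable count and stress code, denominator = units with that
syllable count and any defined stress code; undefined when the target has
no stress code or the denominator is empty. A unit's code comes from its
first member carrying a stress mark. Counting units (types) rather than
frequency mass follows the "proportion of words" reading; a
frequency-weighted variant would be a different statistic, deliberately not
offered.

## Validation and the CLI

Every malformed input maps to one fixed diagnostic (missing/locked/
undecodable files, empty cells, the 3-column corpus rule, the
digits-and-one-dot frequency grammar, metric/data availability, the
20-unique-items rule, the stress-mark requirement). The CLI validates
everything and computes all rows before the output file is created, so a
failed run never leaves a partial file; exit status 1 marks validation
errors (message verbatim on stderr), 2 usage errors. One `--regime` flag
governs the whole density/frequency family per run; covering both regimes
means running twice. Floats are written at full `repr` precision — no
rounding is specified anywhere, and rounding would corrupt downstream
matching.

## Synthetic corpora and what the tests show

The generator produces n distinct spellings over a small alphabet (lengths
uniform in a range), rank-frequency following a Zipf law with exponent 1.0
by default — a reasonable stand-in for natural token distributions — and,
optionally, pronunciations via a per-letter grapheme-phoneme map (which
guarantees tokenizability) with an optional initial-stress mark. It is
deterministic under its seed.

The oracle suite compares every engine metric against an independent naive
reimplementation (recursive memoized Levenshtein, exhaustive pairwise
scans) on 200 seeded corpora of 5–60 words, lengths ≤ 8, alphabets of 3–5
letters; agreement is exact (1e-9 on floats). With a bijective
letter-phoneme map, orthographic and phonological metrics are verified to
coincide, a strong internal consistency check on the sequence-generic
engine. These corpora are small and combinatorially dense compared with
real lexicons; they exercise correctness, not scale, and they do not
emulate real orthography-phonology correlations, morphology, or realistic
grapheme-phoneme many-to-many mappings. Correctness on them therefore
transfers to real corpora only insofar as the metrics are pure functions of
the lexicon — which they are — not because the corpora are linguistically
realistic. Problem sizes throughout (corpus counts, 5,000–10,000 tokenizer
round-trip trials) were chosen to exhaust the behavior space of the small
sequences involved while keeping the full suite comfortably fast on one
CPU.

## Known limitations

- No grapheme-to-phoneme conversion, syllabification beyond vowel counting,
  secondary stress, or transposition edits.
- Neighbor scans are O(n·L²) per target; intended for desk-scale corpora
  (tens of thousands of rows), not web-scale lexicons.
- Bit-compatibility with other calculators is not claimed: treatment of
  homographs/homophones, the uniqueness-point boundary convention, the SD
  divisor, and the bigram log/smoothing choices all vary across tools and
  are documented above instead.
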