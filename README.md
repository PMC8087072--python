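# lexcalc

`lexcalc` computes the lexical variables psycholinguists use to design and
control word-recognition stimuli — for **any** letter string, including
nonwords like *murp*, against **any** user-supplied corpus and phonetic
system. It is a library plus a small CLI; nothing is tied to a built-in
database, so the same code serves English, French, Spanish, Dutch, German, or
any other alphabetic language for which you can supply a corpus and a
consonant/vowel inventory (built-in IPA, SAMPA, and Klattese inventories ship
with the package).

## Metrics

For a target string *t* and a corpus lexicon *L* (with word frequencies):

- **Surface** — stress code (1-based index of the primary-stressed syllable)
  and stress typicality (proportion of same-syllable-count words sharing the
  target's stress position).
- **Orthographic** — length; neighborhood density and identity (Coltheart's
  *N*: words at one substitution, or at one substitution/addition/deletion);
  neighborhood frequency mean and SD; OLD-20 (mean ± SD Levenshtein distance
  to the 20 closest spellings); spread (number of positions where a single
  substitution yields a neighbor); uniqueness point (earliest prefix length
  at which *t* diverges from every other word); clustering coefficient
  (fraction of neighbor pairs that are neighbors of each other); sum of
  position-specific log₁₀ bigram frequencies.
- **Phonological** — the same family over phoneme tokens (number of phonemes,
  syllables, PND, PLD-20, spread, uniqueness point, C coefficient, sum
  biphone frequency). A diphthong listed as one inventory entry is one
  phoneme.
- **Phonographic** — density, frequency, and C coefficient for words that are
  simultaneously orthographic *and* phonological neighbors.

Homographs and homophones are treated as a single lexical representation:
entries sharing a spelling and/or pronunciation collapse into one unit whose
frequency is the sum of its members (the phonological neighbor "mail/male"
counts once, with frequency *f*(mail)+*f*(male)), and a target's own
homographs/homophones are excluded from its neighborhoods.

## File formats

All files are headerless CSV UTF-8 (comma delimited); row 1 is data.

- **input file** — column 1: orthography; column 2 (optional): pronunciation.
- **corpus file** — column 1: orthography; column 2 (optional):
  pronunciation; final column: word frequency (digits and at most one `.`).
- **phonetic system** — column 1: consonants; column 2: vowels; column 3:
  primary-stress mark. Multi-character cells (diphthongs, affricates) are
  kept whole. Built-in systems: `en_US-IPA`, `en_US-Klattese`,
  `en_US-SAMPA`, `en_UK-IPA`, `en_UK-SAMPA`, `fr-IPA`, `fr-SAMPA`, `es-IPA`,
  `es-SAMPA`, `nl-IPA`, `nl-SAMPA`, `de-IPA`, `de-SAMPA`.

## Worked example

With a six-word corpus (`sail/seɪl/8, mail/meɪl/5, male/meɪl/3, pail/peɪl/4,
pale/peɪl/2, tale/teɪl/1`) and targets `sail` and the nonword `murp`:

```bash
lexcalc --input targets.csv --corpus corpus.csv --output out.csv \
        --with-pronunciation --phonetic-system en_US-IPA \
        --metrics n_phonemes,n_syllables,phonological_density,phonological_frequency
```

`out.csv`:

```text
Words (orthographic),Words (phonological),No. of Phonemes,No. of Syllables,Phonological Neighbourhood Density,Identity of Phonological neighbours (O),Identity of Phonological neighbours (P),Phonological Neighbourhood Frequency (M),Phonological Neighbourhood Frequency (SD)
sail,seɪl,3,1,3,mail/male; pail/pale; tale,meɪl; peɪl; teɪl,5.0,3.605551275463989
murp,mərp,4,1,0,,,,
```

Reading the `sail` row: /seɪl/ has 3 phonemes and 1 syllable (the diphthong
/eɪ/ is one phoneme); its phonological neighborhood holds 3 units — the
homophones *mail*/*male* collapse into one neighbor with combined frequency
5+3=8 — and the mean of the neighbor frequencies {8, 6, 1} is 5.0. The
nonword *murp* is computed identically and simply has no neighbors here.
Empty cells mean "undefined" (e.g. an SD over fewer than two neighbors).

`--metrics default` selects the common battery (number of phonemes and
syllables, orthographic and phonological densities and frequencies under
substitutions/additions/deletions, OLD-20 and PLD-20); `--regime subs`
switches the density/frequency families to substitutions only. The same
computations are available in Python via `lexcalc.compute_table` and the
lower-level functions (`neighbors`, `ld20`, `sum_log_frequency`, ...).

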