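import pytest

from lexcalc import (
    CorpusEntry,
    EditRegime,
    InputRecord,
    MetricSelection,
    ValidationError,
    build_lexicon,
    compute_table,
    default_selection,
    stress_typicality,
    tokenize,
)
from lexcalc.lexicon import collapse
from lexcalc.metrics import (
    DEFAULT_METRICS,
    METRIC_HEADINGS,
    build_views,
    compute_row,
    validate_selection,
)


class TestDefaultSelection:
    def test_contents(self):
        sel = default_selection()
        assert "pld20" in sel.metrics and "old20" in sel.metrics
        assert "stress_typicality" not in sel.metrics
        assert not any(m.startswith("phonographic") for m in sel.metrics)
        assert sel.regime is EditRegime.SUBSTITUTION_ADDITION_DELETION

    def test_rejected_on_orthography_only_data(self):
        with pytest.raises(ValidationError) as err:
            validate_selection(default_selection(), False, None)
        assert (
            str(err.value)
            == "Words (phonological) must not be empty for phonological metrics."
        )

    def test_empty_selection_rejected(self):
        with pytest.raises(ValidationError) as err:
            validate_selection(MetricSelection(()), True, None)
        assert str(err.value) == "No metrics have been selected."

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metrics"):
            MetricSelection(("nope",))


class TestStressTypicality:
    @pytest.fixture()
    def stressed_lexicon(self, ipa):
        # four 2-syllable units, three stressed on syllable 1
        entries = [
            CorpusEntry("bacon", "ˈbeɪkən", 5.0),
            CorpusEntry("apple", "ˈæpəl", 4.0),
            CorpusEntry("able", "ˈeɪbəl", 3.0),
            CorpusEntry("abide", "əˈbaɪd", 2.0),
            CorpusEntry("sail", "ˈseɪl", 9.0),  # different syllable count
        ]
        return build_lexicon(entries, ipa, with_pronunciation=True)

    def test_proportion_among_same_syllable_count(self, stressed_lexicon, ipa):
        view = collapse(stressed_lexicon, "phonological")
        target = tokenize("ˈmæni", ipa)  # 2 syllables, stress on syllable 1
        assert stress_typicality(target, view, ipa) == pytest.approx(0.75)

    def test_unanimous_corpus_gives_one(self, stressed_lexicon, ipa):
        view = collapse(stressed_lexicon, "phonological")
        target = tokenize("ˈsɔ", ipa)  # 1 syllable, like "sail"
        assert stress_typicality(target, view, ipa) == 1.0

    def test_unstressed_target_undefined(self, stressed_lexicon, ipa):
        view = collapse(stressed_lexicon, "phonological")
        assert stress_typicality(tokenize("mæni", ipa), view, ipa) is None

    def test_numerators_partition_denominator(self, stressed_lexicon, ipa):
        view = collapse(stressed_lexicon, "phonological")
        codes = [
            stress_typicality(tokenize(p, ipa), view, ipa)
            for p in ("ˈmæni", "məˈni")  # codes 1 and 2 over 2-syllable units
        ]
        assert sum(codes) == pytest.approx(1.0)


class TestComputeRow:
    def test_orthography_only_row(self, f1_entries):
        lex = build_lexicon(f1_entries)
        sel = MetricSelection(
            ("length", "orthographic_density"), EditRegime.SUBSTITUTION_ONLY
        )
        views = build_views(lex, sel)
        row = compute_row(InputRecord("cat"), lex, views, sel)
        assert row["Length"] == 3
        assert row["Orthographic Neighbourhood Density"] == 6

    def test_nonword_target_computed_normally(self, f1_entries):
        lex = build_lexicon(f1_entries)
        sel = MetricSelection(("orthographic_density",))
        views = build_views(lex, sel)
        row = compute_row(InputRecord("murp"), lex, views, sel)
        assert row["Orthographic Neighbourhood Density"] == 0
        assert row["Identity of Orthographic neighbours"] == ""

    def test_phonological_identity_cells(self, f2_lexicon, ipa):
        sel = MetricSelection(("phonological_density",))
        views = build_views(f2_lexicon, sel)
        row = compute_row(InputRecord("sail", "seɪl"), f2_lexicon, views, sel, ipa)
        assert row["Phonological Neighbourhood Density"] == 3
        assert row["Identity of Phonological neighbours (O)"] == "mail/male; pail/pale; tale"
        assert row["Identity of Phonological neighbours (P)"] == "meɪl; peɪl; teɪl"

    def test_homophone_excluded_from_target_neighborhood(self, f2_lexicon, ipa):
        sel = MetricSelection(("phonological_density",))
        views = build_views(f2_lexicon, sel)
        row = compute_row(InputRecord("pail", "peɪl"), f2_lexicon, views, sel, ipa)
        assert "pale" not in row["Identity of Phonological neighbours (O)"]

    def test_target_in_corpus_matches_outside_computation(self, f1_entries):
        lex = build_lexicon(f1_entries)
        lex_without = build_lexicon(
            [e for e in f1_entries if e.orthography != "cat"]
        )
        sel = MetricSelection(("orthographic_density",))
        row_in = compute_row(
            InputRecord("cat"), lex, build_views(lex, sel), sel
        )
        row_out = compute_row(
            InputRecord("cat"), lex_without, build_views(lex_without, sel), sel
        )
        assert (
            row_in["Orthographic Neighbourhood Density"]
            == row_out["Orthographic Neighbourhood Density"]
        )


class TestPhonographicMetrics:
    @pytest.fixture()
    def pg_lexicon(self, ipa):
        entries = [
            CorpusEntry("sail", "seɪl", 8.0),
            CorpusEntry("mail", "meɪl", 5.0),
            CorpusEntry("male", "meɪl", 3.0),  # phonological but not orthographic nbr
            CorpusEntry("pail", "peɪl", 4.0),
            CorpusEntry("said", "sɛd", 1.0),  # orthographic but not phonological nbr
        ]
        return build_lexicon(entries, ipa, with_pronunciation=True)

    def test_conjunction_of_channels(self, pg_lexicon, ipa):
        sel = MetricSelection(("phonographic_density",))
        views = build_views(pg_lexicon, sel)
        row = compute_row(InputRecord("sail", "seɪl"), pg_lexicon, views, sel, ipa)
        assert row["Phonographic Neighbourhood Density"] == 2
        assert row["Identity of Phonographic neighbours (O)"] == "mail; pail"

    def test_density_bounded_by_both_channels(self, f2_lexicon, ipa):
        sel = MetricSelection(
            ("orthographic_density", "phonological_density", "phonographic_density")
        )
        views = build_views(f2_lexicon, sel)
        for e in f2_lexicon.entries:
            row = compute_row(
                InputRecord(e.orthography, e.pronunciation),
                f2_lexicon,
                views,
                sel,
                ipa,
            )
            assert row["Phonographic Neighbourhood Density"] <= min(
                row["Orthographic Neighbourhood Density"],
                row["Phonological Neighbourhood Density"],
            )

    def test_homophone_or_homograph_excluded(self, pg_lexicon, ipa):
        sel = MetricSelection(("phonographic_density",))
        views = build_views(pg_lexicon, sel)
        # "male" shares the target's pronunciation -> excluded outright
        row = compute_row(InputRecord("mole", "meɪl"), pg_lexicon, views, sel, ipa)
        assert "male" not in row["Identity of Phonographic neighbours (O)"]


class TestComputeTable:
    def test_headings_and_row_order(self, f2_lexicon, ipa):
        records = [InputRecord("sail", "seɪl"), InputRecord("murp", "mərp")]
        # the default set minus LD-20, which needs a 20-unit corpus
        ids = tuple(m for m in DEFAULT_METRICS if m not in ("old20", "pld20"))
        table = compute_table(records, f2_lexicon, MetricSelection(ids), ipa)
        expected = ["Words (orthographic)", "Words (phonological)"]
        for m in ids:
            expected.extend(METRIC_HEADINGS[m])
        assert table.column_headings == expected
        assert [r["Words (orthographic)"] for r in table.rows] == ["sail", "murp"]
        assert all(h in r for r in table.rows for h in expected)

    def test_spread_bounded_by_length(self, f2_lexicon, ipa):
        sel = MetricSelection(
            ("length", "orthographic_spread", "n_phonemes", "phonological_spread")
        )
        table = compute_table(
            [InputRecord("sail", "seɪl")], f2_lexicon, sel, ipa
        )
        row = table.rows[0]
        assert int(row["Orthographic Spread"]) <= int(row["Length"])
        assert int(row["Phonological Spread"]) <= int(row["No. of Phonemes"])

    def test_undefined_metrics_render_empty(self, f2_lexicon, ipa):
        sel = MetricSelection(("stress_code",))
        table = compute_table([InputRecord("tale", "teɪl")], f2_lexicon, sel, ipa)
        assert table.rows[0]["Stress Code"] == ""  # unstressed pronunciation

    def test_surface_without_stress_mark_rejected(self, f2_lexicon):
        from lexcalc import InventorySpec

        bare = InventorySpec(consonants=("s", "m", "p", "t", "l"), vowels=("eɪ",))
        with pytest.raises(ValidationError) as err:
            compute_table(
                [InputRecord("sail", "seɪl")],
                f2_lexicon,
                MetricSelection(("stress_code",)),
                bare,
            )
        assert str(err.value) == "Please specify a stress mark in the phonetic system."

    def test_default_selection_table_errors_small_corpus(self, f2_lexicon, ipa):
        with pytest.raises(ValidationError, match="at least 20 unique items"):
            compute_table(
                [InputRecord("sail", "seɪl")],
                f2_lexicon,
                default_selection(),
                ipa,
            )
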