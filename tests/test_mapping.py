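import pytest
from hypothesis import given
from hypothesis import strategies as st

from ontofeat._text import normalize, tokenize
from ontofeat.mapping import (
    MappingConfig,
    MappingError,
    MappingResult,
    MappingTable,
    RawTerm,
    export_review_table,
    import_review_table,
    map_corpus,
    map_term,
    match_compositional,
    match_syntactic,
    transform_semantic,
)
from ontofeat.synth import GeneratorConfig, generate


class TestNormalize:
    def test_stopwords_and_punctuation(self):
        assert tokenize("Depletion of neuron in CA2") == ["depletion", "neuron", "ca2"]

    def test_identity_modulo_case(self):
        assert tokenize("CA2") == ["ca2"]

    def test_multiword_with_stopword(self):
        assert tokenize("Heterotropic neuronal nodules at periventricular site") == [
            "heterotropic", "neuronal", "nodules", "periventricular", "site",
        ]

    def test_empty_input(self):
        assert tokenize("") == []
        assert normalize("  ,,  ") == ""

    @given(st.text(max_size=40))
    def test_deterministic_and_idempotent(self, text):
        once = normalize(text)
        assert normalize(text) == once
        assert normalize(once) == once


class TestSyntactic:
    def test_synonym_hit(self, fixture_ontology):
        result = match_syntactic(RawTerm("microglia nodules", "microscopy"), fixture_ontology)
        assert result.classes == {"NodularHeterotopia"}
        assert result.step == "syntactic"

    def test_preferred_label_identity(self, fixture_ontology):
        result = match_syntactic(RawTerm("Nodular Heterotopia", "microscopy"), fixture_ontology)
        assert result.classes == {"NodularHeterotopia"}

    def test_no_hit_is_unmapped(self, fixture_ontology):
        result = match_syntactic(RawTerm("zzqx", "microscopy"), fixture_ontology)
        assert result.step == "unmapped"
        assert not result.classes


class TestCompositional:
    @pytest.mark.parametrize(
        "phrase",
        [
            "depletion of neuron in CA2",
            "segmental cell loss in CA2",
            "neuronal cell loss in CA2",
            "reduced neuronal density in CA2",
        ],
    )
    def test_printed_ca2_compositions(self, fixture_ontology, phrase):
        result = match_compositional(RawTerm(phrase, "microscopy"), fixture_ontology)
        assert result.classes == {"NeuronalLoss", "CA2"}
        assert result.step == "compositional"

    def test_no_subspan_is_unmapped(self, fixture_ontology):
        result = match_compositional(RawTerm("qq zz ww", "microscopy"), fixture_ontology)
        assert result.step == "unmapped"

    def test_residual_tokens_recorded(self, fixture_ontology):
        result = match_compositional(
            RawTerm("neuronal cell loss somewhere unusual here", "microscopy"), fixture_ontology
        )
        assert set(result.residual_tokens) == {"somewhere", "unusual", "here"}


class TestSemantic:
    def test_astroglial_phenotype(self, fixture_ontology):
        result = transform_semantic(RawTerm("astroglial phenotype", "microscopy"), fixture_ontology)
        assert result.classes == {"Astrocyte", "GlialCell", "BrainGlialTumor"}
        assert result.step == "semantic"

    def test_unmatched_stem_is_unmapped(self, fixture_ontology):
        result = transform_semantic(RawTerm("flibbertigibbet", "microscopy"), fixture_ontology)
        assert result.step == "unmapped"

    def test_anchor_without_neighbors_stays_alone(self, fixture_ontology):
        # Vimentin has no parents and no outgoing relations: empty expansion
        result = transform_semantic(RawTerm("vimentins", "immunohistochemistry"), fixture_ontology)
        assert result.classes == {"Vimentin"}


class TestCascade:
    @pytest.mark.parametrize(
        "text,step",
        [
            ("microglia nodules", "syntactic"),
            ("depletion of neuron in CA2", "compositional"),
            ("astroglial phenotype", "semantic"),
        ],
    )
    def test_step_precedence(self, fixture_ontology, text, step):
        assert map_term(RawTerm(text, "microscopy"), fixture_ontology).step == step

    def test_syntactic_wins_even_when_compositional_would_match(self, fixture_ontology):
        # the full phrase is a synonym, so it must never be decomposed
        result = map_term(RawTerm("periventricular nodular heterotropia", "microscopy"), fixture_ontology)
        assert result.step == "syntactic"

    def test_determinism(self, fixture_ontology):
        term = RawTerm("neuronal cell loss in CA3", "microscopy")
        config = MappingConfig()
        assert map_term(term, fixture_ontology, config) == map_term(term, fixture_ontology, config)

    def test_result_invariants(self):
        with pytest.raises(MappingError):
            MappingResult(RawTerm("x", "microscopy"), frozenset({"A", "B"}), "syntactic")
        with pytest.raises(MappingError):
            MappingResult(RawTerm("x", "microscopy"), frozenset(), "semantic")


class TestMapCorpus:
    def test_all_preferred_labels_all_syntactic(self, fixture_ontology):
        from ontofeat.features import Report

        reports = [
            Report("p1", {"microscopy": ("Neuronal Loss", "Balloon Cell")}, ("Gliosis",)),
            Report("p2", {"imaging": ("Mass Lesion",)}, ("Cyst",)),
        ]
        table = map_corpus(reports, fixture_ontology)
        assert all(r.step == "syntactic" for r in table.entries.values())
        assert table.unmapped_report() == []

    def test_noise_free_corpus_matches_ground_truth(self, fixture_ontology):
        reports, truth, ontology = generate(
            GeneratorConfig(n_patients=40, target_vocab=None, lexical_noise_rate=0.0, seed=3)
        )
        table = map_corpus(reports, ontology)
        for key, result in table.entries.items():
            assert result.classes == truth.oracle[key], key

    def test_empty_corpus(self, fixture_ontology):
        assert map_corpus([], fixture_ontology).entries == {}

    def test_consolidation_is_monotone(self, small_corpus, small_mapping):
        reports, _, _ = small_corpus
        distinct_raw = {
            (normalize(t.text), t.category) for r in reports for t in r.iter_terms()
        }
        mapped_keys = set()
        for (text, category), result in small_mapping.entries.items():
            if result.classes:
                mapped_keys.update((category, c) for c in result.classes)
            else:
                mapped_keys.add((category, f"raw:{text}"))
        assert len(mapped_keys) <= len(distinct_raw)


class TestReviewTable:
    def test_round_trip_unchanged(self, fixture_ontology, small_mapping, tmp_path):
        path = tmp_path / "review.tsv"
        export_review_table(small_mapping, path)
        table = MappingTable(entries=dict(small_mapping.entries))
        import_review_table(path, table, fixture_ontology)
        # nothing was approved differently, so entries keep their class sets
        assert {k: v.classes for k, v in table.entries.items()} == {
            k: v.classes for k, v in small_mapping.entries.items()
        }

    def test_approved_override_wins(self, fixture_ontology, tmp_path):
        path = tmp_path / "review.tsv"
        path.write_text(
            "raw_text\tcategory\tclass_ids\tstep\tapproved\n"
            "odd finding\tmicroscopy\tAstrogliosis\treviewed\tyes\n"
        )
        table = MappingTable()
        import_review_table(path, table, fixture_ontology)
        entry = table.entries[("odd finding", "microscopy")]
        assert entry.reviewed and entry.classes == {"Astrogliosis"}

    def test_unknown_category_rejected(self, fixture_ontology, tmp_path):
        path = tmp_path / "review.tsv"
        path.write_text(
            "raw_text\tcategory\tclass_ids\tstep\tapproved\nx\txray\tCA1\tsyntactic\tyes\n"
        )
        with pytest.raises(MappingError, match="xray"):
            import_review_table(path, MappingTable(), fixture_ontology)

    def test_unknown_class_rejected(self, fixture_ontology, tmp_path):
        path = tmp_path / "review.tsv"
        path.write_text(
            "raw_text\tcategory\tclass_ids\tstep\tapproved\nx\tmicroscopy\tGhost\tsyntactic\tyes\n"
        )
        with pytest.raises(MappingError, match="Ghost"):
            import_review_table(path, MappingTable(), fixture_ontology)

    def test_malformed_row_reports_line(self, fixture_ontology, tmp_path):
        path = tmp_path / "review.tsv"
        path.write_text("raw_text\tcategory\tclass_ids\tstep\tapproved\nonly-two\tcols\n")
        with pytest.raises(MappingError, match=":2"):
            import_review_table(path, MappingTable(), fixture_ontology)

    def test_export_empty_table_rejected(self, tmp_path):
        with pytest.raises(MappingError, match="empty"):
            export_review_table(MappingTable(), tmp_path / "x.tsv")

    def test_reviewed_entries_survive_remapping(self, fixture_ontology):
        from ontofeat.features import Report

        table = MappingTable()
        key = ("neuronal loss", "microscopy")
        table.entries[key] = MappingResult(
            RawTerm("neuronal loss", "microscopy"), frozenset({"CA1"}), "reviewed", reviewed=True
        )
        reports = [Report("p1", {"microscopy": ("Neuronal Loss",)}, ("Gliosis",))]
        map_corpus(reports, fixture_ontology, table=table)
        assert table.entries[key].classes == {"CA1"}
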