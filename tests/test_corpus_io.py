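import pytest

from chemtag import corpus_io
from chemtag.corpus_io import (
    Document,
    FormatError,
    Mention,
    PredictionRecord,
    read_abstracts,
    read_annotations,
    read_cdi,
    read_cem,
    write_cdi,
    write_cem,
)


class TestAbstracts:
    def test_three_column_line_maps_to_document(self, tmp_path):
        p = tmp_path / "abs.tsv"
        p.write_text("101\tAspirin study\tWe measured aspirin.\n")
        assert read_abstracts(p) == [
            Document("101", "Aspirin study", "We measured aspirin.")
        ]

    def test_empty_file_gives_empty_corpus(self, tmp_path):
        p = tmp_path / "abs.tsv"
        p.write_text("")
        assert read_abstracts(p) == []

    @pytest.mark.parametrize(
        "content,fragment",
        [
            ("101\tonly two columns\n", ":1"),
            ("101\ta\tb\n101\tc\td\n", "duplicate"),
            ("\ta\tb\n", "empty doc_id"),
        ],
    )
    def test_malformed_lines_raise_with_location(self, tmp_path, content, fragment):
        p = tmp_path / "abs.tsv"
        p.write_text(content)
        with pytest.raises(FormatError, match=fragment):
            read_abstracts(p)

    def test_round_trip_identity(self, tmp_path):
        docs = [Document("1", "Title one", "Body."), Document("2", "", "")]
        p = tmp_path / "abs.tsv"
        corpus_io.write_abstracts(docs, p)
        assert read_abstracts(p) == docs


class TestAnnotations:
    docs = [Document("101", "Aspirin study", "The id CHEBI:28262 appeared.")]

    def test_valid_row_passes_substring_check(self, tmp_path):
        p = tmp_path / "gold.tsv"
        p.write_text("101\tT\t0\t7\tAspirin\ttrivial\n")
        (m,) = read_annotations(p, self.docs)
        assert (m.section, m.start, m.end, m.text) == ("T", 0, 7, "Aspirin")

    def test_identifier_entity_type_accepted(self, tmp_path):
        p = tmp_path / "gold.tsv"
        p.write_text("101\tA\t7\t18\tCHEBI:28262\tidentifier\n")
        (m,) = read_annotations(p, self.docs)
        assert m.entity_type == "identifier"

    def test_offset_text_mismatch_rejected_not_repaired(self, tmp_path):
        p = tmp_path / "gold.tsv"
        p.write_text("101\tT\t0\t7\tBspirin\ttrivial\n")
        with pytest.raises(FormatError, match="101"):
            read_annotations(p, self.docs)

    def test_unknown_entity_type_rejected(self, tmp_path):
        p = tmp_path / "gold.tsv"
        p.write_text("101\tT\t0\t7\tAspirin\tdrug\n")
        with pytest.raises(FormatError, match="entity_type"):
            read_annotations(p, self.docs)

    def test_round_trip(self, tmp_path, toy_corpus):
        p = tmp_path / "gold.tsv"
        corpus_io.write_annotations(toy_corpus.gold, p)
        back = read_annotations(p, toy_corpus.documents)
        assert [m.span_key for m in back] == [m.span_key for m in toy_corpus.gold]


class TestPredictions:
    def test_cem_line_serialization(self, tmp_path):
        p = tmp_path / "cem.tsv"
        write_cem([PredictionRecord("101", "A:12:19", 1, 0.99)], p)
        assert p.read_text() == "101\tA:12:19\t1\t0.99\n"

    def test_rank_gap_is_an_error(self, tmp_path):
        recs = [
            PredictionRecord("1", "alpha", 1, 0.9),
            PredictionRecord("1", "beta", 3, 0.5),
        ]
        with pytest.raises(FormatError, match="rank"):
            write_cdi(recs, tmp_path / "cdi.tsv")

    def test_duplicate_cdi_term_is_an_error(self, tmp_path):
        recs = [
            PredictionRecord("1", "alpha", 1, 0.9),
            PredictionRecord("1", "alpha", 2, 0.5),
        ]
        with pytest.raises(FormatError, match="duplicate"):
            write_cdi(recs, tmp_path / "cdi.tsv")

    def test_empty_prediction_set_gives_empty_file(self, tmp_path):
        p = tmp_path / "cem.tsv"
        write_cem([], p)
        assert p.read_text() == ""
        assert read_cem(p) == []

    def test_round_trip_cem_and_cdi(self, tmp_path):
        cem = [
            PredictionRecord("1", "T:0:7", 1, 1.0),
            PredictionRecord("1", "A:3:9", 2, 0.123456),
            PredictionRecord("2", "A:0:2", 1, 0.5),
        ]
        cdi = [
            PredictionRecord("1", "aspirin", 1, 0.99),
            PredictionRecord("1", "DMSO", 2, 0.75),
        ]
        pc, pd = tmp_path / "cem.tsv", tmp_path / "cdi.tsv"
        write_cem(cem, pc)
        write_cdi(cdi, pd)
        assert read_cem(pc) == cem
        assert read_cdi(pd) == cdi
        # write(read(x)) is byte-identical
        pc2 = tmp_path / "cem2.tsv"
        write_cem(read_cem(pc), pc2)
        assert pc2.read_bytes() == pc.read_bytes()

    def test_malformed_cem_payload_rejected(self, tmp_path):
        p = tmp_path / "cem.tsv"
        p.write_text("1\tX:0:7\t1\t0.5\n")
        with pytest.raises(FormatError, match="payload"):
            read_cem(p)


class TestAuxiliaryFormats:
    def test_stop_word_file_with_comments(self, tmp_path):
        p = tmp_path / "stop.txt"
        p.write_text("# header\nin  # inline comment\nas\n\nwater solution\n")
        assert corpus_io.read_stop_words(p) == ["in", "as", "water solution"]

    def test_pattern_file(self, tmp_path):
        p = tmp_path / "pat.tsv"
        p.write_text("LY\tLY[\\ ]{0,1}[1-9][0-9]{5,6}\n")
        assert corpus_io.read_patterns(p) == [("LY", "LY[\\ ]{0,1}[1-9][0-9]{5,6}")]

    def test_lexicon_rows_validation(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("aspirin\tC1\tdb\t2\n")
        with pytest.raises(FormatError, match="has_structure"):
            corpus_io.read_lexicon_rows(p)
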