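import random

import pytest

from chemtag.corpus_io import Document
from chemtag.lexicon import StopWordList
from chemtag.recognizers import (
    RecognizerError,
    compile_patterns,
    match_identifiers,
    run_external,
    tag_dictionary,
    toy_grammar,
)
from chemtag.synthetic import packaged_patterns
from chemtag.tokenizer import token_boundaries

from conftest import make_lexicon


def brute_force_matches(text, lexicon):
    """Independent oracle: enumerate every boundary-aligned substring, keep
    the longest match per start, then drop matches wholly covered by a longer
    match from the same lexicon."""
    bounds = sorted(token_boundaries(text))
    per_start = []
    for i, s in enumerate(bounds):
        best = None
        for e in bounds[i + 1 :]:
            if text[s:e] in lexicon:
                best = e
        if best is not None:
            per_start.append((s, best))
    return [
        h
        for h in per_start
        if not any(o != h and o[0] <= h[0] and h[1] <= o[1] for o in per_start)
    ]


class TestDictionaryTagger:
    def test_title_match(self):
        doc = Document("101", "Aspirin study", "")
        lex = make_lexicon(["aspirin"])
        out = tag_dictionary(doc, lex)
        (m,) = out.mentions
        assert (m.section, m.start, m.end, m.text) == ("T", 0, 7, "Aspirin")

    def test_leftmost_longest_and_covered_suppression(self):
        doc = Document("1", "", "acetylsalicylic acid")
        lex = make_lexicon(["acetylsalicylic acid", "acid"])
        out = tag_dictionary(doc, lex)
        assert [(m.start, m.end) for m in out.mentions] == [(0, 20)]

    def test_stop_word_filtering_removes_ambiguous_match(self):
        doc = Document("1", "", "In vivo")
        lex = make_lexicon(["In"], mode="sensitive")
        stop = StopWordList("basic-english", ["in"])
        assert tag_dictionary(doc, lex, [stop]).mentions == []

    def test_mentions_satisfy_substring_invariant(self, toy_corpus, toy_lexicon):
        for doc in toy_corpus.documents:
            for m in tag_dictionary(doc, toy_lexicon).mentions:
                assert doc.section_text(m.section)[m.start : m.end] == m.text

    @pytest.mark.parametrize("mode", ["insensitive", "sensitive", "partial"])
    def test_oracle_equivalence_random_fixtures(self, mode):
        """tag_dictionary equals brute-force boundary-aligned search."""
        rng = random.Random(42)
        vocab = ["alpha", "beta", "Gamma", "acid", "salt water", "x-1,2-ol",
                 "DMSO", "(CH3)2SO", "NaCl2", "of", "the", "in"]
        for trial in range(60):
            terms = rng.sample(vocab, rng.randint(1, 8))
            lex = make_lexicon(terms, mode=mode)
            words = [rng.choice(vocab + ["filler", "words", "here"])
                     for _ in range(rng.randint(1, 40))]
            text = " ".join(words)[:500]
            doc = Document("d", "", text)
            got = [(m.start, m.end) for m in tag_dictionary(doc, lex).mentions]
            assert got == sorted(brute_force_matches(text, lex))


class TestIdentifierRecognizer:
    patterns = compile_patterns(packaged_patterns())

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("LY541850", ["LY541850"]),
            ("LY 2090314", ["LY 2090314"]),
            ("LY041850", []),  # first digit must be 1-9
            ("see CHEBI:28262 and AMN082", ["CHEBI:28262"]),
        ],
    )
    def test_ly_pattern_family(self, text, expected):
        doc = Document("1", "", text)
        out = match_identifiers(doc, self.patterns)
        assert [m.text for m in out.mentions] == expected

    def test_mentions_carry_identifier_type(self):
        doc = Document("1", "", "compound LY541850 here")
        (m,) = match_identifiers(doc, self.patterns).mentions
        assert m.entity_type == "identifier" and m.sources == ("regex",)

    def test_insensitive_to_pattern_file_order(self):
        doc = Document("1", "", "DB00328 then HMDB40292 then LY541850")
        fwd = match_identifiers(doc, self.patterns).mentions
        rev = match_identifiers(doc, list(reversed(self.patterns))).mentions
        assert [(m.start, m.end) for m in fwd] == [(m.start, m.end) for m in rev]

    def test_invalid_pattern_names_the_culprit(self):
        with pytest.raises(ValueError, match="BROKEN"):
            compile_patterns([("BROKEN", "a{3,1}")])


class TestExternalAdapters:
    def test_toy_grammar_finds_systematic_name(self):
        doc = Document("1", "", "We tested 2-Acetoxybenzoic acid today")
        out = run_external(doc, toy_grammar, "toy", entity_type="systematic")
        assert [m.text for m in out.mentions] == ["2-Acetoxybenzoic acid"]
        assert out.mentions[0].entity_type == "systematic"

    def test_invalid_spans_dropped_and_counted(self):
        doc = Document("1", "short", "tiny")
        adapter = lambda t, a: [("A", 0, 99), ("T", 0, 5), ("A", 3, 2), "junk"]
        out = run_external(doc, adapter, "sloppy")
        assert [m.text for m in out.mentions] == ["short"]
        assert out.n_rejected == 3

    def test_empty_adapter_output(self):
        doc = Document("1", "a", "b")
        out = run_external(doc, lambda t, a: [], "quiet")
        assert out.mentions == [] and out.n_rejected == 0

    def test_adapter_failure_labeled_with_system_name(self):
        def boom(t, a):
            raise RuntimeError("kaput")

        with pytest.raises(RecognizerError, match="crashy"):
            run_external(Document("1", "a", "b"), boom, "crashy")
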