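import math

import pytest
from scipy.stats import spearmanr

from chemtag.corpus_io import documents_by_id, validate_mention
from chemtag.evaluation import evaluate_cem
from chemtag.ensemble import resolve_overlaps
from chemtag.lexicon import normalize
from chemtag.ranking import score_from_ratio, term_ratio
from chemtag.recognizers import tag_dictionary
from chemtag.synthetic import (
    SynthesisConfig,
    generate_corpus,
    generate_frequency_tables,
)
from chemtag.tokenizer import token_boundaries

from conftest import build_lexicon


class TestCorpusGeneration:
    def test_fixture_set_is_byte_identical_under_fixed_seed(self, tmp_path):
        cfg = SynthesisConfig(n_documents=12, rng_seed=11)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_corpus(cfg).write(d1)
        generate_corpus(cfg).write(d2)
        files1 = sorted(p.name for p in d1.iterdir())
        assert files1 == sorted(p.name for p in d2.iterdir())
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_gold_offsets_verified_against_text(self, toy_corpus):
        docs = documents_by_id(toy_corpus.documents)
        for mention in toy_corpus.gold:
            validate_mention(mention, docs)

    def test_entity_type_mix_covers_all_eight_types(self):
        corpus = generate_corpus(SynthesisConfig(n_documents=120, rng_seed=2))
        assert {m.entity_type for m in corpus.gold} == {
            "trivial", "systematic", "abbreviation", "formula",
            "identifier", "family", "multiple", "undefined",
        }

    def test_zero_overlap_rate_means_no_nested_gold_spans(self):
        corpus = generate_corpus(
            SynthesisConfig(n_documents=20, overlap_rate=0.0, rng_seed=5)
        )
        assert corpus.nested_gold_spans == 0
        lex = build_lexicon(corpus.lexicon_rows)
        docs = documents_by_id(corpus.documents)
        for g in corpus.gold:
            text = docs[g.doc_id].section_text(g.section)
            bounds = sorted(
                b for b in token_boundaries(text) if g.start <= b <= g.end
            )
            nested = [
                (s, e)
                for i, s in enumerate(bounds)
                for e in bounds[i + 1 :]
                if (s, e) != (g.start, g.end) and text[s:e] in lex
            ]
            assert not nested, f"gold {g.text!r} nests lexicon term(s) {nested}"

    def test_nonzero_overlap_rate_produces_nested_structure(self, toy_corpus):
        assert toy_corpus.nested_gold_spans > 0

    def test_perfect_dictionary_limit_has_recall_one(self):
        corpus = generate_corpus(
            SynthesisConfig(n_documents=25, ambiguity_rate=0.0, rng_seed=3)
        )
        lex = build_lexicon(corpus.lexicon_rows)
        predicted = [
            m for doc in corpus.documents for m in tag_dictionary(doc, lex).mentions
        ]
        result = evaluate_cem(corpus.gold, resolve_overlaps(predicted))
        assert result.recall == 1.0

    def test_ambiguous_terms_occur_annotated_and_unannotated(self, toy_corpus):
        docs = documents_by_id(toy_corpus.documents)
        annotated = {m.text for m in toy_corpus.gold if m.text in toy_corpus.ambiguous_terms}
        assert annotated, "no ambiguous term was ever annotated"
        gold_spans = {m.span_key for m in toy_corpus.gold}
        lex = build_lexicon(toy_corpus.lexicon_rows)
        unannotated = 0
        for doc in toy_corpus.documents:
            for m in tag_dictionary(doc, lex).mentions:
                if m.text in toy_corpus.ambiguous_terms and m.span_key not in gold_spans:
                    unannotated += 1
        assert unannotated > 0

    def test_identifier_golds_match_shipped_patterns(self, toy_corpus):
        from chemtag.recognizers import compile_patterns, match_identifiers

        patterns = compile_patterns(toy_corpus.patterns)
        docs = documents_by_id(toy_corpus.documents)
        for g in toy_corpus.gold:
            if g.entity_type != "identifier":
                continue
            spans = {
                (m.section, m.start, m.end)
                for m in match_identifiers(docs[g.doc_id], patterns).mentions
            }
            assert (g.section, g.start, g.end) in spans


class TestFrequencyTables:
    def test_neutral_enrichment_scores_near_half(self):
        model = generate_frequency_tables(
            {f"t{i}": 1.0 for i in range(300)}, seed=4, mean_occurrences=50
        )
        scores = [score_from_ratio(term_ratio(t, model)) for t in model.term_counts]
        mean = sum(scores) / len(scores)
        assert mean == pytest.approx(0.5, abs=0.05)

    def test_infinite_enrichment_scores_one(self):
        model = generate_frequency_tables({"always": math.inf}, seed=1)
        assert score_from_ratio(term_ratio("always", model)) == 1.0

    def test_enrichment_recovery_rank_correlation(self):
        # Monte-Carlo recovery: estimated scores must track true enrichment
        import numpy as np

        rng = np.random.default_rng(12)
        enrichment = {f"term{i:03d}": float(10 ** rng.uniform(-1, 1)) for i in range(200)}
        model = generate_frequency_tables(enrichment, seed=12)
        est = [score_from_ratio(term_ratio(t, model)) for t in sorted(enrichment)]
        true = [enrichment[t] for t in sorted(enrichment)]
        rho = spearmanr(true, est).statistic
        assert rho > 0.8

    def test_enriched_terms_outscore_depleted_terms(self, toy_corpus):
        hi, lo = [], []
        for term, e in toy_corpus.enrichment.items():
            score = score_from_ratio(term_ratio(term, toy_corpus.model))
            (hi if e > 1 else lo).append(score)
        assert hi and lo
        assert sum(hi) / len(hi) > sum(lo) / len(lo)
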