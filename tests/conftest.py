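import pytest

from chemtag import Lexicon, SynthesisConfig, generate_corpus


def build_lexicon(rows, mode="partial", name="synthdb"):
    lex = Lexicon(name, mode)
    for term, cid, src, hs in rows:
        lex.add(term, cid, src, hs)
    return lex


def make_lexicon(terms, mode="insensitive", name="lex"):
    lex = Lexicon(name, mode)
    for i, term in enumerate(terms):
        lex.add(term, f"C{i:04d}", name, True)
    return lex


@pytest.fixture(scope="session")
def toy_corpus():
    """A small deterministic synthetic corpus shared across tests."""
    return generate_corpus(SynthesisConfig(n_documents=30, rng_seed=7))


@pytest.fixture(scope="session")
def toy_lexicon(toy_corpus):
    return build_lexicon(toy_corpus.lexicon_rows)
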