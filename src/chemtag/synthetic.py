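"""Self-contained synthetic fixtures for every stage of the pipeline.

The generator emits a miniature annotated corpus in the same shape as a
CHEMDNER-style release: abstracts with title/abstract sections, gold
stand-off annotations over all eight entity types, a lexicon covering the
gold vocabulary, stop-word lists, an identifier pattern file, and a
two-corpus term-frequency table with controlled enrichment.  Everything is
deterministic under ``rng_seed``.

Controlled structure:

* ``ambiguity_rate`` — fraction of lexicon terms that are also common words
  (metal names such as "iron").  Ambiguous terms occur annotated in chemical
  slots *and* unannotated in carrier prose, so stop-word filtering and
  training adaptation have true signal.
* ``overlap_rate`` — fraction of gold spans drawn from multiword systematic
  terms whose tail word ("acid", "acetate", "ester") is itself a lexicon
  entry, producing nested candidate matches for overlap resolution.  At rate
  zero no tail entries are added and no gold span nests a lexicon term.
* ``enrichment`` — per-term factor by which the term is enriched in the
  chemical corpus; the frequency table is sampled so the expected raw count
  ratio equals enrichment x (n_chem / n_nonchem), i.e. the normalized ratio
  estimates the enrichment directly.
"""

from __future__ import annotations

import math
import os
import random
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .corpus_io import (
    Document,
    Mention,
    documents_by_id,
    validate_mention,
    write_abstracts,
    write_annotations,
    write_lexicon_rows,
    write_stop_words,
)
from .ranking import ConfidenceModel, write_frequency_table

ENTITY_TYPE_DEFAULTS = {
    "trivial": 18,
    "systematic": 14,
    "abbreviation": 10,
    "formula": 8,
    "identifier": 8,
    "family": 8,
    "multiple": 3,
    "undefined": 5,
}

# prose vocabulary; deliberately excludes "and" so multiword "X and Y" gold
# terms can never be forged by adjacent slots
_CARRIER = (
    "the study measured increased patients cells after during treatment with "
    "results analysis showed significant we observed levels effect compared "
    "control group data using between both further also which these this were "
    "was for from within reported assay baseline cohort dose response exposure "
    "samples tissue plasma serum outcome marked reduced slightly"
).split()

# common words a chemical lexicon may share with ordinary English
_AMBIGUOUS_POOL = (
    "iron gold mercury zinc copper nickel tin arsenic carbon radium "
    "antimony platinum"
).split()

_SYLLABLES = (
    "an ben cet dro fen gly hex lor meth nor oxa pro sal tri vin zol phen "
    "chlor eth but dex quin mab flu ket ran tam"
).split()

_STOP_LIST_FILES = {
    "basic-english": "stop_basic_english.txt",
    "pubmed": "stop_pubmed.txt",
    "jochem-style": "stop_jochem_style.txt",
    "guideline-style": "stop_guideline_style.txt",
}

DEFAULT_FALLBACK_PRECISION = {"regex": 0.90, "grammar": 0.75, "dictionary": 0.65}


def packaged_stop_lists() -> dict[str, list[str]]:
    """The four toy stop-word lists shipped with the package."""
    out: dict[str, list[str]] = {}
    for name, fname in _STOP_LIST_FILES.items():
        text = resources.files("chemtag.data").joinpath(fname).read_text("utf-8")
        out[name] = [
            line.split("#", 1)[0].strip()
            for line in text.splitlines()
            if line.split("#", 1)[0].strip()
        ]
    return out


def packaged_patterns() -> list[tuple[str, str]]:
    """The shipped identifier pattern file as (name, pattern) rows."""
    text = (
        resources.files("chemtag.data")
        .joinpath("identifier_patterns.tsv")
        .read_text("utf-8")
    )
    return [tuple(line.split("\t", 1)) for line in text.splitlines() if line.strip()]


@dataclass
class SynthesisConfig:
    n_documents: int = 50
    terms_per_type: dict[str, int] = field(
        default_factory=lambda: dict(ENTITY_TYPE_DEFAULTS)
    )
    ambiguity_rate: float = 0.1
    overlap_rate: float = 0.15
    enrichment: dict[str, float] | None = None
    rng_seed: int = 0
    n_chem: int = 50_000
    n_nonchem: int = 20_000
    mean_occurrences: float = 8.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ambiguity_rate <= 1.0):
            raise ValueError("ambiguity_rate must be in [0,1]")
        if not (0.0 <= self.overlap_rate <= 1.0):
            raise ValueError("overlap_rate must be in [0,1]")
        if self.n_documents < 0:
            raise ValueError("n_documents must be >= 0")
        if any(v < 0 for v in self.terms_per_type.values()):
            raise ValueError("term counts must be >= 0")


@dataclass
class SyntheticCorpus:
    documents: list[Document]
    gold: list[Mention]
    lexicon_rows: list[tuple[str, str, str, bool]]
    stop_lists: dict[str, list[str]]
    patterns: list[tuple[str, str]]
    enrichment: dict[str, float]
    model: ConfidenceModel
    ambiguous_terms: list[str]
    nested_gold_spans: int
    config: SynthesisConfig

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        """Write all fixture files plus a ready-to-run config; returns paths."""
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "abstracts": os.path.join(outdir, "abstracts.tsv"),
            "gold": os.path.join(outdir, "gold.tsv"),
            "lexicon": os.path.join(outdir, "lexicon.tsv"),
            "patterns": os.path.join(outdir, "patterns.tsv"),
            "frequency_table": os.path.join(outdir, "freq.tsv"),
            "config": os.path.join(outdir, "config.txt"),
        }
        write_abstracts(self.documents, paths["abstracts"])
        write_annotations(self.gold, paths["gold"])
        write_lexicon_rows(self.lexicon_rows, paths["lexicon"])
        with open(paths["patterns"], "w", encoding="utf-8") as fh:
            for name, pattern in self.patterns:
                fh.write(f"{name}\t{pattern}\n")
        write_frequency_table(self.model.term_counts, paths["frequency_table"])
        stop_lines = []
        for name, terms in self.stop_lists.items():
            fname = f"stop_{name.replace('-', '_')}.txt"
            path = os.path.join(outdir, fname)
            write_stop_words(terms, path)
            paths[f"stoplist:{name}"] = path
            stop_lines.append(f"stoplist = {fname}")
        with open(paths["config"], "w", encoding="utf-8") as fh:
            fh.write("abstracts = abstracts.tsv\n")
            fh.write("lexicon = lexicon.tsv partial synthdb\n")
            fh.write("\n".join(stop_lines) + "\n")
            fh.write("patterns = patterns.tsv\n")
            fh.write("grammar = toy\n")
            fh.write("frequency_table = freq.tsv\n")
            fh.write(f"n_chem = {self.model.n_chem}\n")
            fh.write(f"n_nonchem = {self.model.n_nonchem}\n")
            fh.write(f"seed = {self.config.rng_seed}\n")
            for system, prec in DEFAULT_FALLBACK_PRECISION.items():
                fh.write(f"precision = {system} {prec}\n")
        return paths


class _TermFactory:
    """Unique, collision-checked surface terms for each entity type."""

    def __init__(self, rng: random.Random, forbidden: set[str]):
        self.rng = rng
        self.taken: set[str] = set()
        self.forbidden = {w.casefold() for w in forbidden}

    def _fresh(self, make) -> str:
        for _ in range(1000):
            term = make()
            key = term.casefold()
            if key not in self.taken and key not in self.forbidden:
                self.taken.add(key)
                return term
        raise RuntimeError("term space exhausted; reduce terms_per_type")

    def trivial(self) -> str:
        return self._fresh(
            lambda: "".join(self.rng.sample(_SYLLABLES, self.rng.randint(2, 3)))
            + self.rng.choice(("ine", "ol", "in", "ide", "ate", "one"))
        )

    def systematic(self, multiword: bool) -> str:
        def make() -> str:
            locant = self.rng.choice(("2", "3", "1,2", "2,4", "1,3", "4"))
            stem = "".join(self.rng.sample(_SYLLABLES, 2))
            if multiword:
                end = self.rng.choice(("oic acid", "yl acetate", "yl ester"))
            else:
                end = self.rng.choice(("ane", "ene", "ol", "yl", "oate"))
            return f"{locant}-{stem}{end}"

        return self._fresh(make)

    def abbreviation(self) -> str:
        def make() -> str:
            letters = "".join(
                self.rng.choice("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
                for _ in range(self.rng.randint(3, 4))
            )
            if self.rng.random() < 0.4:
                letters += str(self.rng.randint(1, 9))
            return letters

        return self._fresh(make)

    def formula(self) -> str:
        def make() -> str:
            kind = self.rng.randint(0, 2)
            if kind == 0:
                return (
                    f"C{self.rng.randint(2, 20)}H{self.rng.randint(2, 40)}"
                    f"O{self.rng.randint(1, 9)}"
                )
            if kind == 1:
                return f"(CH{self.rng.randint(2, 4)}){self.rng.randint(2, 3)}SO"
            return (
                self.rng.choice(("Na", "K", "Ca", "Mg", "Fe"))
                + self.rng.choice(("Cl", "Br", "SO4", "NO3"))
                + str(self.rng.randint(2, 4))
            )

        return self._fresh(make)

    def identifier(self) -> str:
        def make() -> str:
            kind = self.rng.randint(0, 7)
            r = self.rng
            if kind == 0:
                return f"LY{r.randint(100000, 9999999)}"
            if kind == 1:
                return f"LY {r.randint(100000, 9999999)}"
            if kind == 2:
                return f"AMN{r.randint(100, 99999)}"
            if kind == 3:
                return f"CHEBI:{r.randint(1, 999999)}"
            if kind == 4:
                return f"CHEMBL{r.randint(100, 9999999)}"
            if kind == 5:
                return f"DB{r.randint(0, 99999):05d}"
            if kind == 6:
                return f"HMDB{r.randint(0, 99999):05d}"
            return f"{r.randint(10, 9999999)}-{r.randint(0, 99):02d}-{r.randint(0, 9)}"

        return self._fresh(make)

    def family(self) -> str:
        return self._fresh(
            lambda: "".join(self.rng.sample(_SYLLABLES, 2))
            + self.rng.choice(("azines", "olines", "amides", "anes", "idines"))
        )

    def multiple(self) -> str:
        def make() -> str:
            a = "".join(self.rng.sample(_SYLLABLES, 2))
            b = "".join(self.rng.sample(_SYLLABLES, 2))
            suffix = self.rng.choice(("ol", "ane", "ene"))
            return f"{a}{suffix} and {b}{suffix}"

        return self._fresh(make)

    def undefined(self) -> str:
        return self._fresh(
            lambda: f"C{self.rng.randint(1, 9)}-"
            f"{self.rng.choice(_SYLLABLES).upper()}-PEG{self.rng.randint(1, 12)}"
        )


class _DocBuilder:
    """Accumulates one section's text while recording gold offsets."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0
        self.gold: list[tuple[int, int, str, str]] = []

    def word(self, w: str) -> None:
        if self.parts:
            self.length += 1  # joining space
        self.parts.append(w)
        self.length += len(w)

    def term(self, term: str, etype: str, annotate: bool = True) -> None:
        if self.parts:
            self.length += 1
        start = self.length
        self.parts.append(term)
        self.length += len(term)
        if annotate:
            self.gold.append((start, self.length, term, etype))

    def punct(self, p: str) -> None:
        # attaches without a preceding space
        self.parts[-1] = self.parts[-1] + p
        self.length += len(p)

    @property
    def text(self) -> str:
        return " ".join(self.parts)


def _build_term_pool(
    config: SynthesisConfig, rng: random.Random, stop_terms: set[str]
) -> tuple[list[tuple[str, str]], list[str], set[str]]:
    """Returns (term, type) pool, ambiguous terms, nested-tail set."""
    forbidden = set(_CARRIER) | stop_terms
    factory = _TermFactory(rng, forbidden)
    pool: list[tuple[str, str]] = []
    nested_tails: set[str] = set()
    for etype, count in config.terms_per_type.items():
        for i in range(count):
            if etype == "trivial":
                term = factory.trivial()
            elif etype == "systematic":
                multiword = config.overlap_rate > 0 and rng.random() < max(
                    config.overlap_rate, 0.3
                )
                term = factory.systematic(multiword)
                if multiword:
                    nested_tails.add(term.rsplit(" ", 1)[1])
            elif etype == "abbreviation":
                term = factory.abbreviation()
            elif etype == "formula":
                term = factory.formula()
            elif etype == "identifier":
                term = factory.identifier()
            elif etype == "family":
                term = factory.family()
            elif etype == "multiple":
                term = factory.multiple()
            elif etype == "undefined":
                term = factory.undefined()
            else:
                raise ValueError(f"unknown entity type {etype!r}")
            pool.append((term, etype))
    n_ambiguous = round(config.ambiguity_rate * len(pool))
    ambiguous = _AMBIGUOUS_POOL[: min(n_ambiguous, len(_AMBIGUOUS_POOL))]
    pool.extend((term, "trivial") for term in ambiguous)
    return pool, list(ambiguous), nested_tails


def generate_corpus(config: SynthesisConfig | None = None) -> SyntheticCorpus:
    """Generate documents, gold annotations, lexicon, stop lists and patterns.

    Every gold mention is validated against the generated text before the
    corpus is returned, and identifier-type golds are drawn from the same
    templates as the shipped pattern file.
    """
    config = config or SynthesisConfig()
    rng = random.Random(config.rng_seed)
    stop_lists = packaged_stop_lists()
    stop_terms = {t for terms in stop_lists.values() for t in terms}
    pool, ambiguous, nested_tails = _build_term_pool(config, rng, stop_terms)
    nested_pool = [
        (t, e) for t, e in pool if e == "systematic" and t.rsplit(" ", 1)[-1] in nested_tails
    ]

    documents: list[Document] = []
    gold: list[Mention] = []
    nested_count = 0

    def pick_term() -> tuple[str, str, bool]:
        if nested_pool and rng.random() < config.overlap_rate:
            term, etype = rng.choice(nested_pool)
            return term, etype, True
        term, etype = rng.choice(pool)
        return term, etype, term.rsplit(" ", 1)[-1] in nested_tails

    for d in range(config.n_documents):
        doc_id = str(1000 + d)
        title = _DocBuilder()
        title.word(rng.choice(_CARRIER).capitalize())
        for _ in range(rng.randint(2, 4)):
            title.word(rng.choice(_CARRIER))
        if pool and rng.random() < 0.6:
            term, etype, nested = pick_term()
            title.term(term, etype)
            nested_count += nested
            title.word(rng.choice(_CARRIER))

        abstract = _DocBuilder()
        for s in range(rng.randint(2, 4)):
            abstract.word(rng.choice(_CARRIER).capitalize())
            n_words = rng.randint(4, 8)
            n_slots = rng.randint(0, 2) if pool else 0
            slot_at = set(rng.sample(range(n_words), n_slots)) if n_slots else set()
            for i in range(n_words):
                if i in slot_at:
                    term, etype, nested = pick_term()
                    abstract.term(term, etype)
                    nested_count += nested
                elif ambiguous and rng.random() < 0.12:
                    abstract.term(rng.choice(ambiguous), "trivial", annotate=False)
                else:
                    abstract.word(rng.choice(_CARRIER))
            abstract.punct(".")

        doc = Document(doc_id, title.text, abstract.text)
        documents.append(doc)
        for section, builder in (("T", title), ("A", abstract)):
            for start, end, text, etype in builder.gold:
                gold.append(Mention(doc_id, section, start, end, text, entity_type=etype))

    docs_by_id = documents_by_id(documents)
    for m in gold:
        validate_mention(m, docs_by_id)

    lexicon_rows = [
        (term, f"SYN:{i:05d}", "synthdb", etype != "family")
        for i, (term, etype) in enumerate(pool)
    ]
    lexicon_rows.extend(
        (tail, f"SYN:T{j:03d}", "synthdb", False)
        for j, tail in enumerate(sorted(nested_tails))
    )

    enrichment = dict(config.enrichment or {})
    if not enrichment:
        for term, _ in pool:
            if term in ambiguous:
                enrichment[term] = round(10 ** rng.uniform(-1.3, -0.1), 4)
            else:
                enrichment[term] = round(10 ** rng.uniform(0.3, 2.0), 4)
    model = generate_frequency_tables(
        enrichment,
        n_chem=config.n_chem,
        n_nonchem=config.n_nonchem,
        mean_occurrences=config.mean_occurrences,
        seed=rng.randrange(2**31),
    )
    model.fallback_precision = dict(DEFAULT_FALLBACK_PRECISION)

    return SyntheticCorpus(
        documents=documents,
        gold=gold,
        lexicon_rows=lexicon_rows,
        stop_lists=stop_lists,
        patterns=packaged_patterns(),
        enrichment=enrichment,
        model=model,
        ambiguous_terms=list(ambiguous),
        nested_gold_spans=nested_count,
        config=config,
    )


def generate_frequency_tables(
    enrichment: dict[str, float],
    n_chem: int = 50_000,
    n_nonchem: int = 20_000,
    mean_occurrences: float = 8.0,
    seed: int = 0,
) -> ConfidenceModel:
    """Sample a two-corpus frequency table with known enrichment.

    For a term with enrichment ``e`` the non-chemical count is Poisson with
    mean ``mean_occurrences`` and the chemical count is Poisson with mean
    ``mean_occurrences * e * n_chem / n_nonchem``, so the expected raw count
    ratio is ``e`` times the corpus-size ratio and the normalized frequency
    ratio estimates ``e``.  ``e = inf`` pins the non-chemical count to zero.
    """
    rng = np.random.default_rng(seed)
    size_ratio = n_chem / n_nonchem
    counts: dict[str, tuple[int, int]] = {}
    for term in sorted(enrichment):
        e = enrichment[term]
        if e < 0:
            raise ValueError(f"enrichment must be nonnegative, got {e} for {term!r}")
        if math.isinf(e):
            c_chem = int(rng.poisson(mean_occurrences * size_ratio)) + 1
            counts[term] = (c_chem, 0)
            continue
        c_nonchem = int(rng.poisson(mean_occurrences))
        c_chem = int(rng.poisson(mean_occurrences * e * size_ratio))
        if c_chem + c_nonchem == 0:
            c_nonchem = 1  # keep the term observable
        counts[term] = (c_chem, c_nonchem)
    return ConfidenceModel(
        term_counts=counts,
        n_chem=n_chem,
        n_nonchem=n_nonchem,
        fallback_precision=dict(DEFAULT_FALLBACK_PRECISION),
    )
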