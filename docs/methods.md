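# Methods

This note documents the models and procedures implemented in `chemtag`, the
conventions they assume, and what the synthetic fixtures do and do not show
about behavior on real literature.

## Data model and offsets

A corpus is a set of documents, each with a title (`T`) and abstract (`A`)
section. All character offsets are 0-based, half-open, counted in Unicode
code points, and indexed *per section*: the title and abstract are addressed
independently. Every mention — gold or predicted — must satisfy the
substring invariant (its stored text equals the section slice at its
offsets); readers reject violations rather than repairing them, since a
silent off-by-one would corrupt exact-boundary evaluation downstream.

Eight entity types are recognized in annotations: abbreviation, family,
formula, identifier, multiple, systematic, trivial, undefined. Evaluation
ignores the type; it exists for error analysis (the per-system unique-TP
breakdown) and for the synthetic generator's type mix.

## Tokenization

Chemical names break ordinary tokenizers: locant commas
("1,2-dichloroethane"), hyphens, and matched brackets in formulas
("(CH3)2SO") are part of the name, while the same characters at a sentence
boundary are punctuation. The tokenizer splits on whitespace, then within
each chunk peels sentence punctuation (`.,;:?!`) and unmatched brackets off
the edges, and keeps `-`, `'`, `,` internal when flanked by alphanumerics,
`.` when flanked by digits, and brackets when matched within the chunk.
Tokens carry exact offsets; the token-boundary set (all starts and ends) is
what the dictionary tagger anchors matches to.

Two properties are enforced by tests: the tokenizer is total and lossless
(tokens are sorted, non-overlapping, substring-exact, and cover every
non-whitespace character of arbitrary Unicode input), and re-tokenizing a
word or chemical token yields that token back.

Deliberate limitation: a fully parenthesized name such as "(nano-WC)" stays
one token, so the inner formula is not separately addressable. This mirrors
a known failure mode of boundary-anchored chemical taggers and is pinned in
the test suite rather than patched, because any local fix (splitting all
brackets) destroys formula tokens like "(CH3)2SO" that matter more often.
No sentence splitting is performed; nothing in the pipeline needs it and
offsets stay per-section.

## Lexicons and matching modes

A lexicon maps normalized terms to `(compound_id, source, has_structure)`
triples. Three modes: `sensitive` (exact surface), `insensitive`
(case-folded), and `partial` — case-sensitive only for abbreviation-like
terms, defined as terms where capitals plus digits form a *strict* majority
of all characters (punctuation counts toward the minority; exactly half does
not qualify). "BaTiO3" (4 of 6) keeps its case; "Aspirin" folds. Partial
mode is the default in generated configs because it protects short
abbreviations ("In", "As" as element symbols vs. prepositions) without
losing case-variant coverage for ordinary names.

Term bookkeeping reports distinct surface terms *before* normalization, so
resource statistics remain comparable across modes.

Stop-word filtering removes a mention when its full surface appears in any
active list, compared case-insensitively (published stop lists mix
capitalization). Multi-word entries are allowed and compared against the
whole surface. Four toy lists ship with the package (basic-english, pubmed,
jochem-style, guideline-style); real lists are drop-in replacements.

## Recognizers

**Dictionary tagger.** A span `[s, e)` is emitted iff `s` and `e` are token
boundaries, the normalized substring is a lexicon key, no longer
boundary-aligned match starts at `s` (leftmost-longest per start), and no
longer match from the same lexicon wholly covers it. Stop-word filtering
follows. The implementation is a bounded scan over boundary pairs with a
hash lookup per candidate; its semantics are pinned by a brute-force oracle
(exhaustive enumeration of all boundary-aligned substrings) that the test
suite runs over a thousand random section texts. Matches may span token
gaps, which is how multi-word terms ("acetylsalicylic acid") are found.

**Identifier regexes.** Patterns run on the raw section text — identifiers
like "LY 2090314" legitimately cross token boundaries. Each pattern is
wrapped with guards `(?<![A-Za-z0-9]) … (?![0-9])` so it can neither fire
inside a longer alphanumeric run nor cut a digit sequence short. The shipped
pattern file covers research-code and database-identifier shapes (LY, AMN,
CHEBI, CHEMBL, DB, HMDB, CAS, CID); it is user-replaceable. Matches carry
entity type `identifier`.

**Grammar plugins.** External systematic-name recognizers participate
through a minimal contract: any callable `(title, abstract) → iterable of
(section, start, end)`. Returned spans are validated against the substring
invariant; invalid spans are dropped and counted (`n_rejected`) rather than
raised, because a third-party tool's occasional bad offset should not abort
a corpus run — a crashing adapter, by contrast, is an error labeled with the
system name. A deliberately small `toy_grammar` (locant prefixes or chemical
infixes plus nomenclature suffixes, absorbing a following "acid"/"acetate"/
"ester") ships as a working example and test fixture; it makes no claim to
parse real nomenclature.

## Ensemble

Merging takes the union of all recognizer outputs; identical spans collapse
into one mention pooling all contributing systems. An optional voting filter
keeps spans found by at least `t` systems (each lexicon and each recognizer
counts once per span); it is monotone in `t` by construction.

Overlap resolution treats any shared character position within one section
as a conflict. Mentions are processed sorted by (document, section, start,
−length) and resolved greedily: a candidate survives only if it beats every
already-kept mention it overlaps, evicting them when it does. The pairwise
rule: longer wins; at equal length, approach priority (regex > grammar >
dictionary, a multi-system mention counting under its best approach); at
equal priority, a coin flip from a `random.Random(rng_seed)` stream. The
greedy sweep makes the pairwise rules total and order-stable, and the seeded
stream makes full pipeline output byte-reproducible — both properties are
tested, including pairwise non-overlap on random conflict sets.

Training adaptation compares predictions with gold on the same documents:
gold surfaces with no exact-boundary prediction become new dictionary terms;
predicted surfaces matching no gold span become new stop words. On a corpus
with dictionary gaps and ambiguous false-positive terms, re-running with the
augmented dictionary raises recall and re-running with the augmented stop
list raises precision; the fully adapted run may trade a little recall for
precision (an ambiguous term annotated once but wrong ten times is worth
stop-listing), so only F-score non-decrease is asserted for the combination.

## Confidence model and CDI ranking

The confidence of a term being chemical comes from contrasting two corpora:
abstracts from chemical journals (size n₁) and from non-chemical journals
(size n₀). With occurrence counts c₁ and c₀:

    ratio = (c₁/n₁) / (c₀/n₀)
    score = ratio·0.5 if ratio < 1 else 1 − 0.5/ratio

Counts are term occurrences, not document frequencies. The per-corpus-size
normalization makes the ratio a relative-frequency ratio; under a shared-idf
reading of tf·idf the idf factor cancels, which is the interpretation that
reproduces the reference worked examples exactly (counts 15,421 vs 1 and 779
vs 101 at corpus sizes 1,979,485 vs 73,603 give 0.99 and 0.14 at two
decimals). `c₀ = 0` yields ratio +∞ and score exactly 1; a term with zero
counts in both corpora carries no signal and is treated as unknown.

Numerical conventions: scores are clamped to [0, 1] and never rounded
internally; serialization writes up to six decimals with trailing zeros
trimmed; *reported* two-decimal scores are truncated toward zero rather than
rounded, so a strongly enriched but finite term (score 0.9991) prints as
0.99, not 1.00 — a confidence of 1.00 is reserved for terms never seen in
the non-chemical corpus.

CDI ranking: per document, unique surfaces (case-sensitive) are scored by
the model when counts exist, otherwise by the highest fallback precision
among the systems that found the term ("the highest score applies" when
several systems overlap). Sorting is by descending score with ties broken
by order of first occurrence; ranks are 1..k with no gaps.

## Evaluation

CEM: a true positive requires identical (document, section, start, end);
entity type is ignored; identical spans are deduplicated before counting.
CDI: true positives are case-sensitive (document, term) matches. Both
micro-average: TP/FP/FN are pooled over the corpus before precision = TP/(TP+FP),
recall = TP/(TP+FN), F = 2PR/(P+R), with 0 conventions for empty
denominators. Macro (per-document) averaging was rejected to stay consistent
with challenge-style corpus-level tables. Ranks and confidences do not enter
P/R/F. The unique-TP breakdown attributes a gold span to a system only when
exactly one system found it.

## Synthetic fixtures

The generator emulates the structural features the pipeline is sensitive to,
not real chemistry prose. Per entity type it fabricates surface forms with
the right shape (syllable-built trivial names; locant + stem + suffix
systematic names, some multiword; uppercase abbreviations; bracketed
formulas; identifiers drawn from the same templates as the shipped pattern
file; pluralized family names; "X and Y" conjunctions; alphanumeric-dash
undefined codes) and embeds them in carrier-word sentences, recording gold
offsets during construction and validating every mention against the text
before returning.

Tunable structure, with defaults chosen to keep every downstream behavior
observable at small corpus sizes:

* `n_documents` (50) — fixtures run in milliseconds yet contain ~3 gold
  mentions per document;
* `ambiguity_rate` (0.1) — fraction of lexicon terms that are also common
  words (metal names); these occur annotated in chemical slots and
  unannotated in prose, giving stop-word filtering and adaptation true
  positives *and* true negatives to distinguish;
* `overlap_rate` (0.15) — fraction of gold spans drawn from multiword
  systematic terms whose tail word is itself a lexicon entry, producing
  nested candidates for overlap resolution; at 0 the corpus provably
  contains no gold span nesting a lexicon term;
* `enrichment` — per-term chemical-corpus enrichment; defaults are
  log-uniform in [2, 100] for chemical terms and [0.05, 0.8] for ambiguous
  ones.

Frequency tables are sampled per term as independent Poisson counts with
non-chemical mean `mean_occurrences` (8) and chemical mean
`mean_occurrences · e · n₁/n₀`, over stand-in corpus sizes n₁ = 50,000 and
n₀ = 20,000, so the expected raw count ratio is the enrichment times the
corpus-size ratio and the normalized ratio estimates `e` directly. A
recovery test checks Spearman ρ > 0.8 between true enrichment and estimated
score at 200 terms.

What passing these fixtures does **not** show: performance on real
abstracts. Real chemical text has morphology the generator does not imitate
(genuine nomenclature grammar, abbreviation definitions, conjunction
ellipsis like "thieno[2,3-d] and thieno[3,2-d] fused…", OCR noise), real
lexicons are five orders of magnitude larger (requiring a trie or automaton
rather than this boundary-pair scan if throughput matters), and real
ambiguity is not confined to a closed list of metal names. The fixtures
verify the *contracts* — matching semantics, merge/resolution rules, score
arithmetic, format round-trips — not corpus-level accuracy.

## Problem sizes used in the checks

The oracle-equivalence suite compares tagger and brute force on 500
generated documents (two sections each, ≤ 500 characters) against sampled
50-term lexicons; transform properties are checked on 10⁴ random ratios;
overlap resolution on 200 random conflict sets plus constructed pairs; the
analytic confidence targets are pure arithmetic. The whole suite runs in a
few seconds on one core.

## Known limitations

* The boundary-pair dictionary scan is O(boundaries × terms-length bound)
  per section — right for abstracts and test corpora, not for
  Medline-scale indexing.
* Partial case-sensitivity classifies by character counts only; it cannot
  rescue an abbreviation that is also a common uppercase word.
* The regex guard `(?![0-9])` forbids a match immediately followed by a
  digit; an identifier dialect that legitimately abuts digits would need a
  pattern-level override.
* Overlap resolution is greedy and pairwise; a globally optimal (weighted
  interval scheduling) selection could differ on pathological chains of
  equal-length overlaps.
* CDI term matching is case-sensitive end to end; if gold annotations are
  case-normalized by an upstream tool, scores will understate agreement.
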