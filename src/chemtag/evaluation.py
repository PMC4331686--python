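"""BioCreative-style scoring for the two tasks.

CEM (mention recognition) counts a true positive only on an exact boundary
match — same document, section, start and end; entity type is ignored.  CDI
(document indexing) matches unique (document, term) pairs case-sensitively.
Precision, recall and F-score are micro-averaged: TP/FP/FN are pooled over
the whole corpus before the ratios are taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus_io import Document, Mention, documents_by_id, validate_mention


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def evaluate_cem(
    gold: Sequence[Mention],
    predicted: Sequence[Mention],
    documents: Sequence[Document] | Mapping[str, Document] | None = None,
) -> EvalResult:
    """Exact-boundary mention evaluation, micro-averaged over the corpus.

    Identical spans are deduplicated on both sides before counting.  When
    ``documents`` is given, predicted mentions are checked against the
    substring invariant first.
    """
    if documents is not None:
        if not isinstance(documents, Mapping):
            documents = documents_by_id(documents)
        for m in predicted:
            validate_mention(m, documents)
    gold_keys = {m.span_key for m in gold}
    pred_keys = {m.span_key for m in predicted}
    tp = len(gold_keys & pred_keys)
    return EvalResult(tp=tp, fp=len(pred_keys - gold_keys), fn=len(gold_keys - pred_keys))


def _as_term_pairs(
    items: Mapping[str, Iterable[str]] | Iterable[tuple[str, str]],
    *,
    forbid_duplicates: bool,
) -> set[tuple[str, str]]:
    if isinstance(items, Mapping):
        pairs = [(doc, term) for doc, terms in items.items() for term in terms]
    else:
        pairs = list(items)
    seen: set[tuple[str, str]] = set()
    for pair in pairs:
        if pair in seen and forbid_duplicates:
            raise ValueError(
                f"doc {pair[0]}: duplicate CDI term {pair[1]!r} in predictions"
            )
        seen.add(pair)
    return seen


def evaluate_cdi(
    gold: Mapping[str, Iterable[str]] | Iterable[tuple[str, str]],
    predicted: Mapping[str, Iterable[str]] | Iterable[tuple[str, str]],
) -> EvalResult:
    """Document-level unique-term evaluation; matching is case-sensitive."""
    gold_pairs = _as_term_pairs(gold, forbid_duplicates=False)
    pred_pairs = _as_term_pairs(predicted, forbid_duplicates=True)
    tp = len(gold_pairs & pred_pairs)
    return EvalResult(
        tp=tp, fp=len(pred_pairs - gold_pairs), fn=len(gold_pairs - pred_pairs)
    )


def cdi_terms_from_mentions(mentions: Sequence[Mention]) -> dict[str, list[str]]:
    """Unique surfaces per document, in order of first occurrence."""
    out: dict[str, dict[str, None]] = {}
    for m in sorted(mentions, key=lambda m: (m.doc_id, m.section != "T", m.start)):
        out.setdefault(m.doc_id, {}).setdefault(m.text)
    return {doc: list(terms) for doc, terms in out.items()}


def unique_tp_breakdown(
    gold: Sequence[Mention],
    outputs: Mapping[str, Sequence[Mention]],
) -> dict[str, dict[str, int]]:
    """True positives attributable to exactly one system, by entity type.

    A gold span found by two or more systems counts for none of them; the
    breakdown shows what each recognizer contributes that no other does.
    """
    gold_by_key = {m.span_key: m for m in gold}
    finders: dict[tuple[str, str, int, int], set[str]] = {}
    for system, mentions in outputs.items():
        for m in mentions:
            if m.span_key in gold_by_key:
                finders.setdefault(m.span_key, set()).add(system)
    breakdown: dict[str, dict[str, int]] = {system: {} for system in outputs}
    for key, systems in finders.items():
        if len(systems) != 1:
            continue
        (system,) = systems
        etype = gold_by_key[key].entity_type or "undefined"
        by_type = breakdown[system]
        by_type[etype] = by_type.get(etype, 0) + 1
    return breakdown
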