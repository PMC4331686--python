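"""Ensemble merging of recognizer outputs.

The ensemble takes the union of all candidate mentions, optionally applies a
voting threshold (a span survives only if enough systems found it), and then
resolves overlaps:

* of two overlapping mentions the longer (more characters) is kept;
* at equal length, the approach priority decides — regular expressions beat
  grammar-based recognizers, which beat dictionary lookups; a mention found
  by several systems counts under its highest-priority system;
* at equal length and priority, a seeded random draw picks the survivor, so
  runs are reproducible.

The training-adaptation step compares predictions with gold annotations:
missed gold surfaces become new dictionary terms, false-positive surfaces
become new stop words.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus_io import Mention
from .recognizers import APPROACHES, RecognizerOutput

_PRIORITY = {approach: rank for rank, approach in enumerate(APPROACHES)}


@dataclass(frozen=True)
class SystemSpec:
    label: str
    approach: str
    precision: float = 0.5

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")
        if not (0.0 <= self.precision <= 1.0):
            raise ValueError("precision estimate must be in [0,1]")


@dataclass
class EnsembleConfig:
    """Systems in play, optional voting threshold, and the tie-break seed."""

    systems: tuple[SystemSpec, ...] = ()
    voting_threshold: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.systems = tuple(self.systems)
        if self.voting_threshold is not None and self.voting_threshold < 1:
            raise ValueError("voting threshold must be >= 1")

    def approach_of(self, label: str) -> str:
        for spec in self.systems:
            if spec.label == label:
                return spec.approach
        return "dictionary"  # unknown systems rank lowest

    def precision_of(self, label: str) -> float:
        for spec in self.systems:
            if spec.label == label:
                return spec.precision
        return 0.5

    def priority(self, mention: Mention) -> int:
        """Best (lowest) approach rank over the mention's sources."""
        if not mention.sources:
            return _PRIORITY["dictionary"]
        return min(_PRIORITY[self.approach_of(s)] for s in mention.sources)


def merge(outputs: Sequence[RecognizerOutput]) -> list[Mention]:
    """Union of all outputs; identical spans collapse, pooling their sources.

    Entity type is taken from the first contributing system that assigned
    one.  Order: document of first appearance, then section (T before A),
    start, end.
    """
    by_span: dict[tuple[str, str, int, int], Mention] = {}
    doc_order: dict[str, int] = {}
    for out in outputs:
        for m in out.mentions:
            doc_order.setdefault(m.doc_id, len(doc_order))
            prev = by_span.get(m.span_key)
            if prev is None:
                by_span[m.span_key] = m
            else:
                sources = tuple(dict.fromkeys(prev.sources + m.sources))
                etype = prev.entity_type or m.entity_type
                by_span[m.span_key] = Mention(
                    m.doc_id, m.section, m.start, m.end, m.text,
                    entity_type=etype, sources=sources,
                )
    return sorted(
        by_span.values(),
        key=lambda m: (doc_order[m.doc_id], m.section != "T", m.start, m.end),
    )


def vote_filter(merged: Sequence[Mention], threshold: int) -> list[Mention]:
    """Keep mentions found by at least ``threshold`` systems."""
    if threshold < 1:
        raise ValueError("voting threshold must be >= 1")
    return [m for m in merged if len(m.sources) >= threshold]


def _overlaps(a: Mention, b: Mention) -> bool:
    return (
        a.doc_id == b.doc_id
        and a.section == b.section
        and a.start < b.end
        and b.start < a.end
    )


def resolve_overlaps(
    mentions: Sequence[Mention], config: EnsembleConfig | None = None
) -> list[Mention]:
    """Greedy pairwise overlap resolution; output is pairwise non-overlapping.

    Mentions are processed sorted by (document, section, start, -length); a
    candidate survives only if it beats every already-kept mention it
    overlaps (longer wins; then approach priority; then a seeded coin flip),
    in which case the beaten mentions are evicted.
    """
    config = config or EnsembleConfig()
    rng = random.Random(config.rng_seed)
    doc_order: dict[str, int] = {}
    for m in mentions:
        doc_order.setdefault(m.doc_id, len(doc_order))
    ordered = sorted(
        mentions,
        key=lambda m: (doc_order[m.doc_id], m.section != "T", m.start, -m.length),
    )
    kept: list[Mention] = []
    for cand in ordered:
        rivals = [k for k in kept if _overlaps(k, cand)]
        wins = True
        for rival in rivals:
            if cand.length != rival.length:
                wins = cand.length > rival.length
            elif config.priority(cand) != config.priority(rival):
                wins = config.priority(cand) < config.priority(rival)
            else:
                wins = rng.random() < 0.5
            if not wins:
                break
        if wins:
            kept = [k for k in kept if k not in rivals]
            kept.append(cand)
    return sorted(
        kept,
        key=lambda m: (doc_order[m.doc_id], m.section != "T", m.start, m.end),
    )


def adapt_from_training(
    gold: Sequence[Mention], predictions: Sequence[Mention]
) -> tuple[list[str], list[str]]:
    """Dictionary and stop-word expansions learned from training errors.

    Returns ``(added_terms, added_stop_words)``: surfaces of gold mentions
    with no exact-boundary prediction, and surfaces of predictions matching
    no gold span.  Both are deduplicated and sorted.
    """
    gold_docs = {m.doc_id for m in gold}
    pred_docs = {m.doc_id for m in predictions}
    if gold_docs and pred_docs and not (gold_docs & pred_docs):
        raise ValueError(
            "gold and predicted mentions cover disjoint document sets"
        )
    gold_keys = {m.span_key for m in gold}
    pred_keys = {m.span_key for m in predictions}
    added_terms = sorted({m.text for m in gold if m.span_key not in pred_keys})
    added_stop = sorted({m.text for m in predictions if m.span_key not in gold_keys})
    return added_terms, added_stop
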