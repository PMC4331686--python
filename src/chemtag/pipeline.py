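"""End-to-end tagging pipeline: the glue the CLI and tests share.

A :class:`PipelineConfig` bundles the loaded resources (lexicons with their
modes, stop lists, identifier patterns, grammar adapters, ensemble settings
and an optional confidence model).  :func:`run_pipeline` applies every
recognizer to every document, merges, optionally vote-filters, resolves
overlaps, and returns the final mentions plus the per-system raw outputs
(needed for unique-TP breakdowns and voting experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .corpus_io import (
    Document,
    Mention,
    PredictionRecord,
    cem_payload,
)
from .ensemble import EnsembleConfig, SystemSpec, merge, resolve_overlaps, vote_filter
from .lexicon import Lexicon, StopWordList
from .ranking import ConfidenceModel, rank_cdi
from .recognizers import (
    GrammarAdapter,
    RegexPattern,
    match_identifiers,
    run_external,
    tag_dictionary,
)


@dataclass
class PipelineConfig:
    lexicons: Sequence[Lexicon] = ()
    stop_lists: Sequence[StopWordList] = ()
    patterns: Sequence[RegexPattern] = ()
    adapters: Mapping[str, GrammarAdapter] = field(default_factory=dict)
    voting_threshold: int | None = None
    rng_seed: int = 0
    model: ConfidenceModel | None = None
    fallback_precision: Mapping[str, float] = field(default_factory=dict)

    def ensemble_config(self) -> EnsembleConfig:
        systems: list[SystemSpec] = []
        if self.patterns:
            systems.append(
                SystemSpec("regex", "regex", self.fallback_precision.get("regex", 0.9))
            )
        for label in self.adapters:
            systems.append(
                SystemSpec(
                    label,
                    "grammar",
                    self.fallback_precision.get(
                        label, self.fallback_precision.get("grammar", 0.75)
                    ),
                )
            )
        for lex in self.lexicons:
            systems.append(
                SystemSpec(
                    lex.name,
                    "dictionary",
                    self.fallback_precision.get(
                        lex.name, self.fallback_precision.get("dictionary", 0.65)
                    ),
                )
            )
        return EnsembleConfig(
            systems=tuple(systems),
            voting_threshold=self.voting_threshold,
            rng_seed=self.rng_seed,
        )


@dataclass
class PipelineResult:
    final: list[Mention]
    merged: list[Mention]
    by_system: dict[str, list[Mention]]
    stage_counts: dict[str, int]


def run_pipeline(
    documents: Sequence[Document], config: PipelineConfig
) -> PipelineResult:
    """Recognize, merge, vote-filter and overlap-resolve over a corpus."""
    by_system: dict[str, list[Mention]] = {}
    outputs = []
    for doc in documents:
        if config.patterns:
            out = match_identifiers(doc, list(config.patterns))
            outputs.append(out)
            by_system.setdefault(out.system, []).extend(out.mentions)
        for label, adapter in config.adapters.items():
            out = run_external(doc, adapter, label, config.stop_lists)
            outputs.append(out)
            by_system.setdefault(out.system, []).extend(out.mentions)
        for lex in config.lexicons:
            out = tag_dictionary(doc, lex, config.stop_lists)
            outputs.append(out)
            by_system.setdefault(out.system, []).extend(out.mentions)
    merged = merge(outputs)
    voted = (
        vote_filter(merged, config.voting_threshold)
        if config.voting_threshold is not None
        else merged
    )
    final = resolve_overlaps(voted, config.ensemble_config())
    return PipelineResult(
        final=final,
        merged=merged,
        by_system=by_system,
        stage_counts={
            "candidates": sum(len(v) for v in by_system.values()),
            "merged": len(merged),
            "voted": len(voted),
            "final": len(final),
        },
    )


def _mention_confidence(
    mention: Mention, config: PipelineConfig
) -> float:
    model = config.model
    if model is not None:
        score = model.score(mention.text)
        if score is not None:
            return score
    ens = config.ensemble_config()
    precisions = [
        (config.model.fallback_precision if config.model else {}).get(
            s, ens.precision_of(s)
        )
        for s in mention.sources
    ]
    return max(precisions, default=0.5)


def cem_records(
    documents: Sequence[Document],
    final: Sequence[Mention],
    config: PipelineConfig,
) -> list[PredictionRecord]:
    """CEM submission records: per document, spans ranked by confidence."""
    records: list[PredictionRecord] = []
    for doc in documents:
        mentions = sorted(
            (m for m in final if m.doc_id == doc.doc_id),
            key=lambda m: (m.section != "T", m.start, m.end),
        )
        scored = [(m, _mention_confidence(m, config)) for m in mentions]
        scored.sort(key=lambda ms: -ms[1])
        for rank, (m, score) in enumerate(scored, start=1):
            records.append(
                PredictionRecord(doc.doc_id, cem_payload(m), rank, min(1.0, max(0.0, score)))
            )
    return records


def cdi_records(
    documents: Sequence[Document],
    final: Sequence[Mention],
    config: PipelineConfig,
) -> list[PredictionRecord]:
    """CDI submission records via the confidence-model ranking."""
    model = config.model or ConfidenceModel(
        fallback_precision=dict(config.fallback_precision)
    )
    records: list[PredictionRecord] = []
    for doc in documents:
        records.extend(
            rank_cdi(doc.doc_id, list(final), model, config.ensemble_config())
        )
    return records
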