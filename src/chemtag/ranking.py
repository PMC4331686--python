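"""Term confidence scores from a two-corpus frequency contrast, and CDI ranking.

The model assumes chemical terms occur more often, per abstract, in journals
about chemistry than in unrelated journals.  For a term with occurrence
counts ``c_chem`` and ``c_nonchem`` in corpora of ``n_chem`` and ``n_nonchem``
abstracts, the normalized frequency ratio

    ratio = (c_chem / n_chem) / (c_nonchem / n_nonchem)

is mapped onto a confidence in [0, 1]:

    score = ratio * 0.5        if ratio < 1
    score = 1 - 0.5 / ratio    otherwise

The transform is continuous (score(1) = 0.5 from both branches), monotone,
and symmetric in the sense score(1/r) = 1 - score(r).  A term never seen in
the non-chemical corpus gets ratio = +inf and score 1.  Terms absent from the
model fall back to the precision of the best system that found them.

Reported two-decimal scores are truncated toward zero rather than rounded,
so a finite ratio never prints as a perfect 1.00.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .corpus_io import FormatError, Mention, PredictionRecord, _tsv_lines
from .ensemble import EnsembleConfig


@dataclass
class ConfidenceModel:
    """Per-term counts in the chemical and non-chemical corpora.

    ``fallback_precision`` maps a system label to the precision used to score
    terms the model has no counts for.
    """

    term_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_chem: int = 1
    n_nonchem: int = 1
    fallback_precision: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_chem < 1 or self.n_nonchem < 1:
            raise ValueError("corpus sizes must be >= 1")
        for term, (c1, c0) in self.term_counts.items():
            if c1 < 0 or c0 < 0:
                raise ValueError(f"negative count for term {term!r}")

    def score(self, term: str) -> float | None:
        """Model score for ``term``, or None when the term is unknown."""
        ratio = term_ratio(term, self)
        return None if ratio is None else score_from_ratio(ratio)


def term_ratio(term: str, model: ConfidenceModel) -> float | None:
    """Normalized chemical/non-chemical frequency ratio; None if unknown.

    A zero non-chemical count yields +inf (handled by the transform); a term
    with zero counts in both corpora carries no signal and is treated as
    unknown.
    """
    counts = model.term_counts.get(term)
    if counts is None:
        return None
    c_chem, c_nonchem = counts
    if c_chem + c_nonchem == 0:
        return None
    if c_nonchem == 0:
        return math.inf
    return (c_chem / model.n_chem) / (c_nonchem / model.n_nonchem)


def score_from_ratio(ratio: float) -> float:
    """Bounded confidence transform of a frequency ratio."""
    if ratio < 0:
        raise ValueError(f"ratio must be nonnegative, got {ratio}")
    if math.isinf(ratio):
        return 1.0
    if ratio < 1.0:
        score = ratio * 0.5
    else:
        score = 1.0 - 0.5 / ratio
    return min(1.0, max(0.0, score))


def truncate_score(score: float, digits: int = 2) -> float:
    """Truncate toward zero at ``digits`` decimals (reporting convention)."""
    factor = 10**digits
    return math.floor(score * factor) / factor


def rank_cdi(
    document_id: str,
    final_mentions: Sequence[Mention],
    model: ConfidenceModel,
    config: EnsembleConfig | None = None,
) -> list[PredictionRecord]:
    """Ranked unique-term list for one document.

    Terms are unique case-sensitively on the surface form; each is scored by
    the confidence model when available, otherwise by the highest fallback
    precision among the systems that found it.  Sorting is by descending
    score, ties broken by order of first occurrence in the document.
    """
    config = config or EnsembleConfig()
    first_seen: dict[str, int] = {}
    term_sources: dict[str, set[str]] = {}
    ordered = sorted(
        (m for m in final_mentions if m.doc_id == document_id),
        key=lambda m: (m.section != "T", m.start, m.end),
    )
    for m in ordered:
        if m.text not in first_seen:
            first_seen[m.text] = len(first_seen)
        term_sources.setdefault(m.text, set()).update(m.sources)

    def fallback(term: str) -> float:
        sources = term_sources.get(term) or set()
        if not sources:
            return 0.5
        return max(
            model.fallback_precision.get(s, config.precision_of(s)) for s in sources
        )

    scored = [
        (term, model.score(term) if model.score(term) is not None else fallback(term))
        for term in first_seen
    ]
    scored.sort(key=lambda ts: (-ts[1], first_seen[ts[0]]))
    return [
        PredictionRecord(document_id, term, rank, min(1.0, max(0.0, score)))
        for rank, (term, score) in enumerate(scored, start=1)
    ]


def read_frequency_table(path: str | os.PathLike) -> dict[str, tuple[int, int]]:
    """TSV rows ``term <TAB> c_chem <TAB> c_nonchem``."""
    counts: dict[str, tuple[int, int]] = {}
    for lineno, line in _tsv_lines(path):
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(
                f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
            )
        term, c1, c0 = parts
        try:
            counts[term] = (int(c1), int(c0))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer count") from exc
    return counts


def write_frequency_table(
    counts: Mapping[str, tuple[int, int]], path: str | os.PathLike
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for term in sorted(counts):
            c1, c0 = counts[term]
            fh.write(f"{term}\t{c1}\t{c0}\n")
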