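"""Readers and writers for the on-disk formats used throughout the pipeline.

All files are UTF-8 TSV (or one-entry-per-line text for stop-word lists).
Character offsets are 0-based, half-open, counted in Unicode code points and
indexed per section: the title (``T``) and the abstract (``A``) of a document
are addressed independently.

Formats
-------
abstracts        ``doc_id <TAB> title <TAB> abstract``
annotations      ``doc_id <TAB> section <TAB> start <TAB> end <TAB> text <TAB> entity_type``
lexicon          ``term <TAB> compound_id <TAB> source <TAB> has_structure``
stop-word list   one term per line, ``#`` starts a comment
pattern file     ``name <TAB> pattern`` per line
CEM predictions  ``doc_id <TAB> SECTION:start:end <TAB> rank <TAB> confidence``
CDI predictions  ``doc_id <TAB> term <TAB> rank <TAB> confidence``
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

ENTITY_TYPES = frozenset(
    {
        "abbreviation",
        "family",
        "formula",
        "identifier",
        "multiple",
        "systematic",
        "trivial",
        "undefined",
    }
)

SECTIONS = ("T", "A")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class Document:
    """One abstract: an opaque identifier plus title and body text."""

    doc_id: str
    title: str
    abstract: str

    def section_text(self, section: str) -> str:
        if section == "T":
            return self.title
        if section == "A":
            return self.abstract
        raise ValueError(f"unknown section {section!r} (expected 'T' or 'A')")


@dataclass(frozen=True)
class Mention:
    """A recognized or gold entity span within one section of a document.

    ``sources`` lists the recognizer systems that produced the span; gold
    mentions leave it empty.  The span is half-open: ``text`` must equal
    ``section_text[start:end]`` of the referenced document.
    """

    doc_id: str
    section: str
    start: int
    end: int
    text: str
    entity_type: str | None = None
    sources: tuple[str, ...] = ()
    score: float | None = None

    def __post_init__(self) -> None:
        if self.section not in SECTIONS:
            raise ValueError(f"section must be 'T' or 'A', got {self.section!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span [{self.start},{self.end}) for doc {self.doc_id}"
            )
        if self.entity_type is not None and self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity_type {self.entity_type!r}")

    @property
    def span_key(self) -> tuple[str, str, int, int]:
        """Identity used for exact-boundary matching and overlap bookkeeping."""
        return (self.doc_id, self.section, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    def with_sources(self, sources: Iterable[str]) -> "Mention":
        return replace(self, sources=tuple(sources))


@dataclass(frozen=True)
class PredictionRecord:
    """One line of a CEM or CDI submission file.

    The payload is a span key ``SECTION:start:end`` for CEM, or a unique
    surface term for CDI.  Ranks are 1..k per document with no gaps.
    """

    doc_id: str
    payload: str
    rank: int
    confidence: float

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")


def validate_mention(mention: Mention, documents: Mapping[str, Document]) -> None:
    """Enforce the substring invariant; never repairs offsets."""
    doc = documents.get(mention.doc_id)
    if doc is None:
        raise FormatError(f"mention references unknown document {mention.doc_id!r}")
    text = doc.section_text(mention.section)
    if mention.end > len(text):
        raise FormatError(
            f"doc {mention.doc_id} section {mention.section}: span "
            f"[{mention.start},{mention.end}) exceeds section length {len(text)}"
        )
    actual = text[mention.start : mention.end]
    if actual != mention.text:
        raise FormatError(
            f"doc {mention.doc_id} section {mention.section} "
            f"[{mention.start},{mention.end}): file says {mention.text!r} "
            f"but section text reads {actual!r}"
        )


def _tsv_lines(path: str | os.PathLike) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            yield lineno, line


def read_abstracts(path: str | os.PathLike) -> list[Document]:
    """Read a corpus of abstracts; order preserved, doc_ids must be unique."""
    docs: list[Document] = []
    seen: set[str] = set()
    for lineno, line in _tsv_lines(path):
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(
                f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
            )
        doc_id, title, abstract = parts
        if not doc_id:
            raise FormatError(f"{path}:{lineno}: empty doc_id")
        if doc_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
        seen.add(doc_id)
        docs.append(Document(doc_id, title, abstract))
    return docs


def write_abstracts(documents: Sequence[Document], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for doc in documents:
            for f in (doc.title, doc.abstract):
                if "\t" in f or "\n" in f:
                    raise FormatError(
                        f"doc {doc.doc_id}: text containing tab/newline cannot be "
                        "serialized as TSV"
                    )
            fh.write(f"{doc.doc_id}\t{doc.title}\t{doc.abstract}\n")


def documents_by_id(documents: Sequence[Document]) -> dict[str, Document]:
    return {d.doc_id: d for d in documents}


def read_annotations(
    path: str | os.PathLike,
    documents: Sequence[Document] | Mapping[str, Document] | None = None,
) -> list[Mention]:
    """Read gold annotations, enforcing the substring invariant.

    ``documents`` may be omitted only when the caller cannot supply the
    corpus; offsets are then taken on faith.
    """
    if documents is not None and not isinstance(documents, Mapping):
        documents = documents_by_id(documents)
    mentions: list[Mention] = []
    for lineno, line in _tsv_lines(path):
        parts = line.split("\t")
        if len(parts) != 6:
            raise FormatError(
                f"{path}:{lineno}: expected 6 tab-separated columns, got {len(parts)}"
            )
        doc_id, section, start_s, end_s, text, etype = parts
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer offsets") from exc
        if etype not in ENTITY_TYPES:
            raise FormatError(f"{path}:{lineno}: unknown entity_type {etype!r}")
        try:
            mention = Mention(doc_id, section, start, end, text, entity_type=etype)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if documents is not None:
            validate_mention(mention, documents)
        mentions.append(mention)
    return mentions


def write_annotations(mentions: Sequence[Mention], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for m in mentions:
            etype = m.entity_type or "undefined"
            fh.write(f"{m.doc_id}\t{m.section}\t{m.start}\t{m.end}\t{m.text}\t{etype}\n")


def read_lexicon_rows(path: str | os.PathLike) -> list[tuple[str, str, str, bool]]:
    """Rows ``(term, compound_id, source, has_structure)`` from a lexicon TSV."""
    rows: list[tuple[str, str, str, bool]] = []
    for lineno, line in _tsv_lines(path):
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(
                f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}"
            )
        term, compound_id, source, flag = parts
        if not term:
            raise FormatError(f"{path}:{lineno}: empty term")
        if flag not in ("0", "1"):
            raise FormatError(f"{path}:{lineno}: has_structure must be 0 or 1")
        rows.append((term, compound_id, source, flag == "1"))
    return rows


def write_lexicon_rows(
    rows: Sequence[tuple[str, str, str, bool]], path: str | os.PathLike
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for term, compound_id, source, has_structure in rows:
            fh.write(f"{term}\t{compound_id}\t{source}\t{int(has_structure)}\n")


def read_stop_words(path: str | os.PathLike) -> list[str]:
    """One term per line; ``#`` starts a comment; blanks ignored."""
    terms: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                terms.append(line)
    return terms


def write_stop_words(terms: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for term in terms:
            fh.write(f"{term}\n")


def read_patterns(path: str | os.PathLike) -> list[tuple[str, str]]:
    """``name <TAB> pattern`` rows for the identifier recognizer."""
    patterns: list[tuple[str, str]] = []
    for lineno, line in _tsv_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(
                f"{path}:{lineno}: expected 'name<TAB>pattern', got {len(parts)} columns"
            )
        patterns.append((parts[0], parts[1]))
    return patterns


def format_confidence(value: float) -> str:
    """Fixed 6-decimal serialization with trailing zeros trimmed.

    ``0.99`` stays ``0.99``; values round-trip exactly through ``float``.
    """
    out = f"{value:.6f}".rstrip("0").rstrip(".")
    return out or "0"


def _check_ranks(records: Sequence[PredictionRecord]) -> None:
    by_doc: dict[str, list[int]] = {}
    for rec in records:
        by_doc.setdefault(rec.doc_id, []).append(rec.rank)
    for doc_id, ranks in by_doc.items():
        if sorted(ranks) != list(range(1, len(ranks) + 1)):
            raise FormatError(
                f"doc {doc_id}: ranks must be 1..{len(ranks)} without gaps or "
                f"duplicates, got {sorted(ranks)}"
            )


def _write_predictions(
    records: Sequence[PredictionRecord], path: str | os.PathLike
) -> None:
    _check_ranks(records)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for rec in records:
            fh.write(
                f"{rec.doc_id}\t{rec.payload}\t{rec.rank}\t"
                f"{format_confidence(rec.confidence)}\n"
            )


def _read_predictions(path: str | os.PathLike) -> list[PredictionRecord]:
    records: list[PredictionRecord] = []
    for lineno, line in _tsv_lines(path):
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(
                f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}"
            )
        doc_id, payload, rank_s, conf_s = parts
        try:
            rec = PredictionRecord(doc_id, payload, int(rank_s), float(conf_s))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        records.append(rec)
    _check_ranks(records)
    return records


def write_cem(records: Sequence[PredictionRecord], path: str | os.PathLike) -> None:
    """Write CEM predictions; payloads must be ``SECTION:start:end`` keys."""
    for rec in records:
        parse_cem_payload(rec.payload)
    _write_predictions(records, path)


def read_cem(path: str | os.PathLike) -> list[PredictionRecord]:
    records = _read_predictions(path)
    for rec in records:
        parse_cem_payload(rec.payload)
    return records


def write_cdi(records: Sequence[PredictionRecord], path: str | os.PathLike) -> None:
    """Write CDI predictions; terms must be unique within a document."""
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.doc_id, rec.payload)
        if key in seen:
            raise FormatError(
                f"doc {rec.doc_id}: duplicate CDI term {rec.payload!r}"
            )
        seen.add(key)
    _write_predictions(records, path)


def read_cdi(path: str | os.PathLike) -> list[PredictionRecord]:
    records = _read_predictions(path)
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.doc_id, rec.payload)
        if key in seen:
            raise FormatError(f"doc {rec.doc_id}: duplicate CDI term {rec.payload!r}")
        seen.add(key)
    return records


def parse_cem_payload(payload: str) -> tuple[str, int, int]:
    """Split ``SECTION:start:end`` into its parts, validating the dialect."""
    parts = payload.split(":")
    if len(parts) != 3 or parts[0] not in SECTIONS:
        raise FormatError(f"malformed CEM payload {payload!r}")
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise FormatError(f"malformed CEM payload {payload!r}") from exc
    if not (0 <= start < end):
        raise FormatError(f"malformed CEM payload {payload!r}")
    return parts[0], start, end


def cem_payload(mention: Mention) -> str:
    return f"{mention.section}:{mention.start}:{mention.end}"
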