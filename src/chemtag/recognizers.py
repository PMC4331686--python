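"""Candidate mention recognizers.

Three kinds of recognizer feed the ensemble:

* :func:`tag_dictionary` — gazetteer matching of lexicon terms, anchored to
  token boundaries, leftmost-longest per start position;
* :func:`match_identifiers` — regular expressions over the raw section text
  for database identifiers such as ``LY541850`` or ``CHEBI:28262``;
* :func:`run_external` — the plugin contract for external grammar-based
  recognizers (systematic-nomenclature parsers); any callable producing
  ``(section, start, end)`` spans can participate.

Overlaps *within* one recognizer are resolved here (a shorter match wholly
covered by a longer match from the same lexicon is suppressed); overlaps
*between* recognizers are deliberately left to the ensemble.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .corpus_io import Document, Mention
from .lexicon import Lexicon, StopWordList, filter_stop_words
from .tokenizer import token_boundaries

APPROACHES = ("regex", "grammar", "dictionary")

# Adapter contract: (title, abstract) -> iterable of (section, start, end).
GrammarAdapter = Callable[[str, str], Iterable[tuple[str, int, int]]]


class RecognizerError(RuntimeError):
    """An external recognizer failed; carries the system label."""


@dataclass
class RecognizerOutput:
    system: str
    approach: str
    mentions: list[Mention] = field(default_factory=list)
    n_rejected: int = 0  # invalid adapter spans dropped, not raised

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")


def _section_matches(
    text: str, lexicon: Lexicon
) -> list[tuple[int, int]]:
    """Boundary-aligned leftmost-longest lexicon matches in one section."""
    if not text or not lexicon.entries:
        return []
    bounds = sorted(token_boundaries(text))
    # small slack: casefolding may change string length (rarely)
    max_len = lexicon.max_term_chars + 4
    per_start: list[tuple[int, int]] = []
    for i, s in enumerate(bounds):
        # longest first: first hit wins for this start
        for e in reversed(bounds[i + 1 :]):
            if e - s > max_len:
                continue
            if text[s:e] in lexicon:
                per_start.append((s, e))
                break
    # suppress matches wholly covered by a longer match from this lexicon
    kept: list[tuple[int, int]] = []
    for s, e in per_start:
        if any(s2 <= s and e <= e2 and (s2, e2) != (s, e) for s2, e2 in per_start):
            continue
        kept.append((s, e))
    return kept


def tag_dictionary(
    document: Document,
    lexicon: Lexicon,
    stop_lists: Sequence[StopWordList] = (),
    system: str | None = None,
) -> RecognizerOutput:
    """Dictionary tagging of one document under the lexicon's matching mode.

    A span ``[s, e)`` is emitted iff both offsets are token boundaries, the
    normalized substring is a lexicon key, no longer boundary-aligned match
    starts at ``s``, and no longer match from this lexicon wholly covers it.
    Matches are then stop-word filtered.
    """
    label = system or lexicon.name
    mentions: list[Mention] = []
    for section in ("T", "A"):
        text = document.section_text(section)
        for s, e in _section_matches(text, lexicon):
            mentions.append(
                Mention(
                    document.doc_id, section, s, e, text[s:e], sources=(label,)
                )
            )
    return RecognizerOutput(
        system=label,
        approach="dictionary",
        mentions=filter_stop_words(mentions, stop_lists),
    )


@dataclass
class RegexPattern:
    """A named identifier pattern, compiled once at construction."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        try:
            # guard against matching inside a longer alphanumeric run or
            # cutting a digit sequence short
            self.compiled = re.compile(
                rf"(?<![A-Za-z0-9])(?:{self.pattern})(?![0-9])"
            )
        except re.error as exc:
            raise ValueError(f"pattern {self.name!r} does not compile: {exc}") from exc


def compile_patterns(patterns: Iterable[tuple[str, str]]) -> list[RegexPattern]:
    return [RegexPattern(name, pat) for name, pat in patterns]


def match_identifiers(
    document: Document,
    patterns: Sequence[RegexPattern],
    system: str = "regex",
) -> RecognizerOutput:
    """Identifier matching on raw section text (no token-boundary constraint).

    Each pattern contributes its non-overlapping, leftmost-longest matches;
    duplicates across patterns collapse.  Output order is (section, start,
    end), independent of pattern-file order.
    """
    spans: set[tuple[str, int, int]] = set()
    for section in ("T", "A"):
        text = document.section_text(section)
        for pat in patterns:
            for m in pat.compiled.finditer(text):
                if m.start() < m.end():
                    spans.add((section, m.start(), m.end()))
    mentions = [
        Mention(
            document.doc_id,
            section,
            s,
            e,
            document.section_text(section)[s:e],
            entity_type="identifier",
            sources=(system,),
        )
        for section, s, e in sorted(spans, key=lambda x: (x[0] != "T", x[1], x[2]))
    ]
    return RecognizerOutput(system=system, approach="regex", mentions=mentions)


def run_external(
    document: Document,
    adapter: GrammarAdapter,
    system: str,
    stop_lists: Sequence[StopWordList] = (),
    entity_type: str | None = None,
) -> RecognizerOutput:
    """Run a grammar-recognizer plugin and validate its spans.

    Spans failing the substring/offset contract are dropped and counted in
    ``n_rejected`` rather than raised; a crashing adapter is an error labeled
    with the system name.
    """
    try:
        raw = list(adapter(document.title, document.abstract))
    except Exception as exc:  # noqa: BLE001 - plugin boundary
        raise RecognizerError(f"external recognizer {system!r} failed: {exc}") from exc
    mentions: list[Mention] = []
    rejected = 0
    for item in raw:
        try:
            section, start, end = item
            text = document.section_text(section)
        except (TypeError, ValueError):
            rejected += 1
            continue
        if not (isinstance(start, int) and isinstance(end, int)):
            rejected += 1
            continue
        if not (0 <= start < end <= len(text)):
            rejected += 1
            continue
        mentions.append(
            Mention(
                document.doc_id,
                section,
                start,
                end,
                text[start:end],
                entity_type=entity_type,
                sources=(system,),
            )
        )
    return RecognizerOutput(
        system=system,
        approach="grammar",
        mentions=filter_stop_words(mentions, stop_lists),
        n_rejected=rejected,
    )


# --- toy grammar recognizer ------------------------------------------------
#
# A deliberately small heuristic for systematic-looking names (locant prefixes
# plus common nomenclature suffixes).  It exists so the plugin contract and the
# ensemble can be exercised without any external tool; it makes no claim to
# parse real nomenclature.

_SYSTEMATIC_TOKEN = re.compile(
    r"""(?<![\w-])
        (?P<locant>[0-9]+(?:,[0-9]+)*-)?   # locant prefix 2- or 1,3-
        (?P<stem>[A-Za-z][a-z]{2,})
        (?:yl|ol|ane|ene|yne|ine|one|ate|ide|oxy|ic)
        (?![\w-])""",
    re.VERBOSE,
)
_ACID_TAIL = re.compile(r"\ (?:acid|acetate|ester)(?![\w-])")
_CHEM_INFIXES = (
    "meth", "eth", "prop", "but", "benz", "phen", "chlor", "fluor", "brom",
    "iod", "hydroxy", "oxo", "acet", "amin", "nitr", "sulf", "carb", "glyc",
)


def toy_grammar(title: str, abstract: str) -> list[tuple[str, int, int]]:
    """Heuristic systematic-name spans; honors the grammar-adapter contract.

    A token qualifies when it has a nomenclature suffix plus either a locant
    prefix or a chemical infix in the stem; a following "acid"/"acetate"/
    "ester" word is absorbed into the span.
    """
    spans: list[tuple[str, int, int]] = []
    for section, text in (("T", title), ("A", abstract)):
        for m in _SYSTEMATIC_TOKEN.finditer(text):
            stem = m.group("stem").lower()
            if not m.group("locant") and not any(x in stem for x in _CHEM_INFIXES):
                continue
            end = m.end()
            tail = _ACID_TAIL.match(text, end)
            if tail:
                end = tail.end()
            spans.append((section, m.start(), end))
    return spans
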