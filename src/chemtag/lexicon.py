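"""Term dictionaries (lexicons) and stop-word lists.

A lexicon maps normalized terms to the compounds they denote.  Three matching
modes are supported:

* ``insensitive`` — all lookups case-folded;
* ``sensitive``   — exact surface matching;
* ``partial``     — case-sensitive only for abbreviation-like terms, i.e.
  terms whose characters are in the majority capitals and digits (e.g.
  "BaTiO3", "DMSO"); everything else is case-folded.

Stop-word filtering removes recognized mentions whose full surface string
appears in any active list; the comparison is case-insensitive because the
published lists mix capitalization ("In" vs "in").
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus_io import Mention, read_lexicon_rows, read_stop_words

MODES = ("insensitive", "sensitive", "partial")


def classify_abbreviation(term: str) -> bool:
    """True iff capitals+digits form a strict majority of all characters.

    Punctuation and whitespace count toward the minority side, so "BaTiO3"
    (4 of 6) qualifies while "aspirin" does not.  Exactly half does not
    qualify.
    """
    if not term:
        raise ValueError("empty term")
    upper_digit = sum(1 for ch in term if ch.isupper() or ch.isdigit())
    return upper_digit > len(term) - upper_digit


def normalize(term: str, mode: str) -> str:
    """Lookup key for ``term`` under a matching mode."""
    if not term:
        raise ValueError("empty term")
    if mode == "sensitive":
        return term
    if mode == "insensitive":
        return term.casefold()
    if mode == "partial":
        return term if classify_abbreviation(term) else term.casefold()
    raise ValueError(f"unknown mode {mode!r} (expected one of {MODES})")


@dataclass
class Lexicon:
    """Normalized term -> {(compound_id, source, has_structure)} under one mode.

    ``n_terms`` counts distinct surface terms before normalization (the
    bookkeeping a resource reports), which may exceed ``len(entries)`` when
    normalization collapses case variants.
    """

    name: str
    mode: str
    entries: dict[str, set[tuple[str, str, bool]]] = field(default_factory=dict)
    n_terms: int = 0
    _surfaces: set[str] = field(default_factory=set, repr=False)
    max_term_chars: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_compounds(self) -> int:
        return len({cid for vals in self.entries.values() for cid, _, _ in vals})

    def add(self, term: str, compound_id: str, source: str = "", has_structure: bool = False) -> None:
        key = normalize(term, self.mode)
        self.entries.setdefault(key, set()).add((compound_id, source, has_structure))
        if term not in self._surfaces:
            self._surfaces.add(term)
            self.n_terms += 1
        self.max_term_chars = max(self.max_term_chars, len(term), len(key))

    def lookup(self, surface: str) -> set[tuple[str, str, bool]] | None:
        return self.entries.get(normalize(surface, self.mode))

    def __contains__(self, surface: str) -> bool:
        return normalize(surface, self.mode) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def load_lexicon(path: str | os.PathLike, mode: str, name: str | None = None) -> Lexicon:
    """Build a lexicon from a TSV of (term, compound_id, source, has_structure)."""
    lex = Lexicon(name=name or os.path.splitext(os.path.basename(os.fspath(path)))[0], mode=mode)
    for term, compound_id, source, has_structure in read_lexicon_rows(path):
        lex.add(term, compound_id, source, has_structure)
    return lex


@dataclass
class StopWordList:
    """A named list of terms excluded from recognition.

    Entries may be multi-word; membership is tested against the full mention
    surface, case-insensitively.
    """

    name: str
    terms: frozenset[str]

    def __init__(self, name: str, terms: Iterable[str]):
        if not name:
            raise ValueError("stop-word list needs a non-empty name")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "terms", frozenset(t.casefold() for t in terms))

    def __contains__(self, surface: str) -> bool:
        return surface.casefold() in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def load_stop_words(path: str | os.PathLike, name: str | None = None) -> StopWordList:
    return StopWordList(
        name or os.path.splitext(os.path.basename(os.fspath(path)))[0],
        read_stop_words(path),
    )


def filter_stop_words(
    mentions: Sequence[Mention], stop_lists: Sequence[StopWordList]
) -> list[Mention]:
    """Drop mentions whose surface appears in any stop list; order preserved."""
    if not stop_lists:
        return list(mentions)
    return [m for m in mentions if not any(m.text in sl for sl in stop_lists)]
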