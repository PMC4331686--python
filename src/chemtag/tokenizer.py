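"""Chemistry-aware tokenization.

Chemical names routinely contain punctuation that ordinary word tokenizers
destroy: locant commas ("1,2-dichloroethane"), hyphens, primes, and matched
brackets in formulas ("(CH3)2SO").  The tokenizer here splits on whitespace,
peels off sentence punctuation and unmatched brackets at chunk edges, and
keeps chemical punctuation internal so such names survive as single tokens.
Token offsets are exact, which lets the dictionary tagger anchor matches to
token boundaries without ever re-deriving positions.

Known-hard cases, kept deliberately: a fully parenthesized name such as
"(nano-WC)" stays one token, so the inner formula is not separately
addressable — mirroring a documented failure mode of boundary-anchored
chemical taggers.
"""

from __future__ import annotations

from dataclasses import dataclass

# punctuation peeled from chunk ends when sentence-final
_SENTENCE_PUNCT = ".,;:?!"
# punctuation kept inside a token when flanked by alphanumerics
_INTERNAL_KEEP = {"-", "'", ","}
_OPEN = {"(": ")", "[": "]", "{": "}"}
_CLOSE = {v: k for k, v in _OPEN.items()}

TOKEN_KINDS = ("word", "number", "punct", "chemical")


@dataclass(frozen=True)
class Token:
    start: int
    end: int
    text: str
    kind: str


def _classify(text: str) -> str:
    if all(ch.isdigit() or ch == "." for ch in text) and any(
        ch.isdigit() for ch in text
    ):
        return "number"
    if all(not ch.isalnum() for ch in text):
        return "punct"
    if text.isalpha():
        return "word"
    # mixed letters/digits/punctuation: the space-free-chemical kind
    return "chemical"


def _matched_bracket_positions(chunk: str) -> set[int]:
    """Positions of brackets that pair up within the chunk."""
    stack: list[tuple[str, int]] = []
    matched: set[int] = set()
    for i, ch in enumerate(chunk):
        if ch in _OPEN:
            stack.append((ch, i))
        elif ch in _CLOSE:
            if stack and stack[-1][0] == _CLOSE[ch]:
                matched.add(stack[-1][1])
                matched.add(i)
                stack.pop()
    return matched


def _split_chunk(chunk: str, offset: int) -> list[tuple[int, int]]:
    """Token spans (absolute offsets) for one whitespace-free chunk."""
    spans: list[tuple[int, int]] = []
    tail: list[tuple[int, int]] = []  # emitted after the core, in order

    lo, hi = 0, len(chunk)
    # peel sentence punctuation off the end, one char at a time
    while hi > lo and chunk[hi - 1] in _SENTENCE_PUNCT:
        tail.insert(0, (offset + hi - 1, offset + hi))
        hi -= 1
    # peel unmatched brackets off both edges
    changed = True
    while changed and hi > lo:
        changed = False
        matched = _matched_bracket_positions(chunk[lo:hi])
        first, last = chunk[lo], chunk[hi - 1]
        if (first in _OPEN and 0 not in matched) or first in _CLOSE:
            spans.append((offset + lo, offset + lo + 1))
            lo += 1
            changed = True
            continue
        if (last in _CLOSE and (hi - lo - 1) not in matched) or last in _OPEN:
            tail.insert(0, (offset + hi - 1, offset + hi))
            hi -= 1
            changed = True
        # re-peel sentence punctuation exposed by a stripped bracket
        while hi > lo and chunk[hi - 1] in _SENTENCE_PUNCT:
            tail.insert(0, (offset + hi - 1, offset + hi))
            hi -= 1
            changed = True

    if hi > lo:
        core = chunk[lo:hi]
        matched = _matched_bracket_positions(core)
        cut_start = 0
        i = 0
        while i < len(core):
            ch = core[i]
            keep = ch.isalnum()
            if not keep and ch in _INTERNAL_KEEP:
                keep = (
                    0 < i < len(core) - 1
                    and core[i - 1].isalnum()
                    and core[i + 1].isalnum()
                )
            if not keep and ch == ".":
                keep = (
                    0 < i < len(core) - 1
                    and core[i - 1].isdigit()
                    and core[i + 1].isdigit()
                )
            if not keep and (ch in _OPEN or ch in _CLOSE):
                keep = i in matched
            if not keep:
                if i > cut_start:
                    spans.append((offset + lo + cut_start, offset + lo + i))
                spans.append((offset + lo + i, offset + lo + i + 1))
                cut_start = i + 1
            i += 1
        if len(core) > cut_start:
            spans.append((offset + lo + cut_start, offset + lo + len(core)))

    spans.extend(tail)
    return spans


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into offset-exact tokens; total on any Unicode input.

    Tokens are non-overlapping, sorted, and cover every non-whitespace
    character, so the original text is reconstructible from tokens plus the
    whitespace between them.
    """
    tokens: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace():
            j += 1
        for s, e in _split_chunk(text[i:j], i):
            tokens.append(Token(s, e, text[s:e], _classify(text[s:e])))
        i = j
    return tokens


def token_boundaries(text: str) -> set[int]:
    """All token starts and ends; the tagger only accepts matches anchored here."""
    bounds: set[int] = set()
    for tok in tokenize(text):
        bounds.add(tok.start)
        bounds.add(tok.end)
    return bounds
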