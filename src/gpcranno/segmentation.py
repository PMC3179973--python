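"""Sentence and token segmentation with exact character offsets.

Every mention produced by the pipeline is a character span into the unchanged
source text (standoff annotation); tokens and sentences are the coordinate
system for the word-distance metric and for same-sentence checks used in
grounding. The splitter is rule-based and deterministic: a sentence ends at a
terminator followed by whitespace and an uppercase/digit start, with an
abbreviation stop-list so "Fig. 3", "et al. (2001)" and "p. 98" do not split,
and decimal numbers like "3.50" (which are also Ballesteros-Weinstein labels)
never split because their period is not followed by whitespace.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Mention:
    """A typed character span in a document. Offsets are 0-based half-open."""

    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"bad span [{self.start}, {self.end})")

    def overlaps(self, other: "Mention") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Mention") -> bool:
        return self.start <= other.start and other.end <= self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int
    sentence_index: int
    token_index: int


@dataclass(frozen=True)
class Sentence:
    start: int
    end: int
    index: int


class AlignmentError(ValueError):
    """A mention does not start and end on token boundaries."""


# Arrows first (so "->" is not split into "-" + ">"), then decimals (so
# "3.50" stays one token), then alphanumeric runs, then single punctuation.
_TOKEN_RE = re.compile(r"-->|->|→|\d+\.\d+|[A-Za-z0-9_]+|[^\sA-Za-z0-9_]")

_TERMINATORS = ".!?"

# Tail patterns (case-insensitive, preceded by a non-letter or string start)
# after which a period never ends a sentence.
_ABBREV_RE = re.compile(
    r"(?:^|[^A-Za-z])"
    r"(?:fig|figs|et\s+al|e\.g|i\.e|vs|cf|ca|dr|no|p|pp|approx|resp|ref|refs)"
    r"\.$",
    re.IGNORECASE,
)


def _is_sentence_break(text: str, i: int) -> bool:
    """True when the terminator at ``text[i]`` ends a sentence."""
    j = i + 1
    if j < len(text) and text[j] in _TERMINATORS:  # part of "..." / "?!"
        return False
    if j >= len(text):
        return True
    if not text[j].isspace():
        return False  # e.g. the period inside "3.50" or "e.g."
    k = j
    while k < len(text) and text[k].isspace():
        k += 1
    if k >= len(text):
        return True
    if not (text[k].isupper() or text[k].isdigit() or text[k] in "(\"'"):
        return False
    if text[i] == "." and _ABBREV_RE.search(text, 0, i + 1):
        return False
    return True


def segment(text: str) -> tuple[list[Sentence], list[Token]]:
    """Split ``text`` into sentences and tokens with exact offsets.

    ``text[t.start:t.end] == t.text`` for every token; tokens are
    non-overlapping, ordered, and each lies inside exactly one sentence.
    Empty text yields two empty lists.
    """
    boundaries: list[int] = []  # exclusive end offsets of sentences
    for i, ch in enumerate(text):
        if ch in _TERMINATORS and _is_sentence_break(text, i):
            boundaries.append(i + 1)
    if not boundaries or boundaries[-1] < len(text):
        if text.strip():
            boundaries.append(len(text))

    sentences: list[Sentence] = []
    prev = 0
    for bound in boundaries:
        start, end = prev, bound
        while start < end and text[start].isspace():
            start += 1
        while end > start and text[end - 1].isspace():
            end -= 1
        if end > start:
            sentences.append(Sentence(start=start, end=end, index=len(sentences)))
        prev = bound

    tokens: list[Token] = []
    sidx = 0
    for m in _TOKEN_RE.finditer(text):
        while sidx + 1 < len(sentences) and m.start() >= sentences[sidx].end:
            sidx += 1
        tokens.append(
            Token(
                text=m.group(),
                start=m.start(),
                end=m.end(),
                sentence_index=sidx,
                token_index=len(tokens),
            )
        )
    return sentences, tokens


def sentence_of(span: Mention, sentences: list[Sentence]) -> int | None:
    """Index of the sentence containing the start of ``span``."""
    for s in sentences:
        if s.start <= span.start < s.end:
            return s.index
    return None


def _align(span: Mention, tokens: list[Token], strict: bool) -> tuple[int, int]:
    """Indices of the first and last token covered by ``span``.

    With ``strict=True`` the span must start on a token start and end on a
    token end, otherwise :class:`AlignmentError`; with ``strict=False`` the
    span is snapped outward to the covering tokens.
    """
    first = last = None
    for t in tokens:
        if t.end <= span.start:
            continue
        if t.start >= span.end:
            break
        if first is None:
            first = t.token_index
        last = t.token_index
    if first is None or last is None:
        raise AlignmentError(f"span [{span.start},{span.end}) covers no token")
    if strict:
        if tokens[first].start != span.start or tokens[last].end != span.end:
            raise AlignmentError(
                f"span [{span.start},{span.end}) not on token boundaries"
            )
    return first, last


def token_distance(
    a: Mention, b: Mention, tokens: list[Token], *, strict: bool = True
) -> int:
    """Number of tokens strictly between two mentions (0 when adjacent).

    Symmetric. This is the word-distance metric used throughout grounding and
    normalization: term combinations close together in the text are favoured
    over more distant ones.
    """
    a_first, a_last = _align(a, tokens, strict)
    b_first, b_last = _align(b, tokens, strict)
    if a_first > b_first:
        a_first, a_last, b_first, b_last = b_first, b_last, a_first, a_last
    return max(0, b_first - a_last - 1)
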