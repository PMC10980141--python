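"""Context-window span extraction for the trainable classifier.

Anchor phrases (the same STB concept dictionary the rule engine uses)
are matched in each note; a window of *n* words to the left and right of
every anchor is extracted, windows are merged where they overlap, and
the merged spans are joined into one text representation per document
carrying the document's gold label. Window sizes of 8, 16, 24 and 32
words are the conventional sweep.

*n* counts word tokens only; punctuation tokens do not consume window
budget but are kept in the rendered text. Windows cross sentence
boundaries and truncate at the document edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .corpus_io import Note
from .lexicon import Lexicon, Sentence, Token, segment_sentences, token_range, tokenize
from .rules import find_concept_mentions

WINDOW_SWEEP: tuple[int, ...] = (8, 16, 24, 32)
SEPARATOR = "[SEP]"
PLACEHOLDER = "[NO_ANCHOR]"


@dataclass(frozen=True)
class AnchorMatch:
    start: int
    end: int
    first_token: int
    last_token: int
    pattern_id: str


@dataclass
class SpanRecord:
    """Combined context windows of one document plus its label."""

    doc_id: str
    text: str
    label: str
    window_token_ranges: list[tuple[int, int]]
    n: int
    scope: str


def match_anchors(
    text: str, tokens: list[Token], sentences: list[Sentence], lexicon: Lexicon
) -> list[AnchorMatch]:
    """All anchor matches (longest-match on overlap), sorted by start."""
    out = []
    for c in find_concept_mentions(text, tokens, sentences, lexicon):
        first, last = token_range(tokens, c.start, c.end)
        out.append(
            AnchorMatch(start=c.start, end=c.end, first_token=first, last_token=last,
                        pattern_id=c.category)
        )
    return out


def _is_word(tok: Token) -> bool:
    return tok.text[0].isalnum()


def extract_context_window(tokens: list[Token], anchor: AnchorMatch, n: int) -> tuple[int, int]:
    """Token interval covering the anchor plus *n* words on each side,
    truncated at the document bounds."""
    if n < 1:
        raise ValueError("window size n must be a positive integer")
    first = anchor.first_token
    count = 0
    i = anchor.first_token - 1
    while i >= 0 and count < n:
        if _is_word(tokens[i]):
            count += 1
            first = i
        i -= 1
    last = anchor.last_token
    count = 0
    i = anchor.last_token + 1
    while i < len(tokens) and count < n:
        if _is_word(tokens[i]):
            count += 1
            last = i
        i += 1
    return (first, last)


def combine_windows(
    intervals: Sequence[tuple[int, int]],
    tokens: list[Token],
    text: str,
    separator: str = SEPARATOR,
    placeholder: str = PLACEHOLDER,
) -> tuple[str, list[tuple[int, int]]]:
    """Merge overlapping/adjacent token intervals and join the rendered
    spans in document order with a single separator token. An empty
    interval list yields the placeholder token."""
    if not intervals:
        return placeholder, []
    merged: list[list[int]] = []
    for first, last in sorted(intervals):
        if merged and first <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], last)
        else:
            merged.append([first, last])
    pieces = [text[tokens[f].start : tokens[l].end] for f, l in merged]
    return f" {separator} ".join(pieces), [(f, l) for f, l in merged]


def build_span_dataset(
    corpus: Sequence[Note],
    gold_labels: Mapping[str, str],
    n: int,
    scope: str,
    lexicon: Lexicon,
) -> list[SpanRecord]:
    """One SpanRecord per document. Anchor-free documents are kept with
    the placeholder text so that they still enter training and
    evaluation; labels are propagated from the document gold labels."""
    missing = [note.note_id for note in corpus if note.note_id not in gold_labels]
    if missing:
        raise KeyError(f"documents missing a {scope} gold label: {missing}")
    records = []
    for note in corpus:
        tokens = tokenize(note.text)
        sentences = segment_sentences(note.text, tokens)
        anchors = match_anchors(note.text, tokens, sentences, lexicon)
        intervals = [extract_context_window(tokens, a, n) for a in anchors]
        text, merged = combine_windows(intervals, tokens, note.text)
        records.append(
            SpanRecord(
                doc_id=note.note_id,
                text=text,
                label=gold_labels[note.note_id],
                window_token_ranges=merged,
                n=n,
                scope=scope,
            )
        )
    return records
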