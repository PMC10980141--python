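"""Rule-based extraction of suicide-history instances from one note.

Pipeline (per note): find STB concept mentions (longest-match,
exclusion-filtered) -> find historical modifiers (explicit phrases and,
optionally, year/date expressions) -> pair each concept with the nearest
same-sentence modifier -> assign polarity with a ConText-style negation
pass (pre/post cues, pseudo-negation, scope termination) -> attribute
personal vs family scope by kinship-term proximity. The result is a
deterministic, offset-sorted list of ``HistoryInstance`` records that the
document classifier aggregates into note-level PSH/FSH labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .lexicon import (
    Lexicon,
    Sentence,
    Token,
    compile_pattern,
    segment_sentences,
    sentence_index_of,
    token_range,
    tokenize,
)

AFFIRMED = "AFFIRMED"
NEGATED = "NEGATED"
PERSONAL = "PERSONAL"
FAMILY = "FAMILY"


@dataclass(frozen=True)
class ConceptMention:
    category: str  # SI | SB | SA
    start: int
    end: int
    matched_text: str
    sentence_index: int


@dataclass(frozen=True)
class ModifierMention:
    start: int
    end: int
    matched_text: str
    kind: str  # explicit_history | temporal
    sentence_index: int


@dataclass(frozen=True)
class HistoryInstance:
    """One extracted mention of suicidal history with polarity and scope."""

    concept: ConceptMention
    modifier: Optional[ModifierMention]
    polarity: str  # AFFIRMED | NEGATED
    scope: str  # PERSONAL | FAMILY

    @property
    def anchor_offset(self) -> int:
        return self.concept.start

    def sort_key(self) -> tuple[int, int, str]:
        return (self.concept.start, self.concept.end, self.concept.category)

    def to_record(self, note_id: str | None = None) -> dict:
        rec = {
            "note_id": note_id,
            "category": self.concept.category,
            "polarity": self.polarity,
            "scope": self.scope,
            "start": self.concept.start,
            "end": self.concept.end,
            "matched_text": self.concept.matched_text,
            "modifier_text": self.modifier.matched_text if self.modifier else None,
            "modifier_kind": self.modifier.kind if self.modifier else None,
        }
        return rec


@dataclass
class ExtractorConfig:
    """Tunable rule parameters (token distances are counted over all
    tokens, punctuation included)."""

    max_pair_distance: int = 10
    negation_scope: int = 6
    family_proximity: int = 5
    enable_temporal_modifiers: bool = True
    #: Count a bare negated concept ("denies SI") as a NEGATED history
    #: instance even without a historical modifier.
    treat_negated_unmodified_as_history: bool = False
    #: Let intrinsically past concepts ("committed suicide") near a
    #: kinship term form a family instance without a modifier.
    relaxed_family_events: bool = True


def _find_matches(text: str, patterns: Sequence[str]) -> list[tuple[int, int]]:
    spans = []
    for pat in patterns:
        rx = compile_pattern(pat)
        spans.extend((m.start(), m.end()) for m in rx.finditer(text))
    return spans


def _resolve_overlaps(cands: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    """Longest match wins; ties broken by leftmost start, then tag."""
    picked: list[tuple[int, int, str]] = []
    for start, end, tag in sorted(cands, key=lambda c: (-(c[1] - c[0]), c[0], c[2])):
        if all(end <= s or start >= e for s, e, _ in picked):
            picked.append((start, end, tag))
    picked.sort()
    return picked


def find_concept_mentions(
    text: str, tokens: list[Token], sentences: list[Sentence], lexicon: Lexicon
) -> list[ConceptMention]:
    """All maximal, non-overlapping target-concept matches, with any
    candidate overlapping an exclusion phrase suppressed."""
    excluded = _find_matches(text, lexicon.exclusions)
    cands: list[tuple[int, int, str]] = []
    for cat, pats in lexicon.target_concepts.items():
        for s, e in _find_matches(text, pats):
            if any(e > xs and s < xe for xs, xe in excluded):
                continue
            cands.append((s, e, cat))
    return [
        ConceptMention(
            category=cat,
            start=s,
            end=e,
            matched_text=text[s:e],
            sentence_index=sentence_index_of(sentences, s),
        )
        for s, e, cat in _resolve_overlaps(cands)
    ]


def find_history_modifiers(
    text: str,
    tokens: list[Token],
    sentences: list[Sentence],
    lexicon: Lexicon,
    include_temporal: bool = True,
) -> list[ModifierMention]:
    cands: list[tuple[int, int, str]] = []
    for s, e in _find_matches(text, lexicon.history_modifiers):
        cands.append((s, e, "explicit_history"))
    if include_temporal:
        for s, e in _find_matches(text, lexicon.temporal_modifiers):
            cands.append((s, e, "temporal"))
    return [
        ModifierMention(
            start=s,
            end=e,
            matched_text=text[s:e],
            kind=kind,
            sentence_index=sentence_index_of(sentences, s),
        )
        for s, e, kind in _resolve_overlaps(cands)
    ]


def _gap_tokens(
    tokens: list[Token], a: tuple[int, int], b: tuple[int, int]
) -> int:
    """Token-index gap between two character spans (0 if they overlap)."""
    a_first, a_last = token_range(tokens, *a)
    b_first, b_last = token_range(tokens, *b)
    if b_first > a_last:
        return b_first - a_last
    if a_first > b_last:
        return a_first - b_last
    return 0


def pair_concept_modifier(
    concepts: list[ConceptMention],
    modifiers: list[ModifierMention],
    tokens: list[Token],
    max_pair_distance: int = 10,
) -> list[tuple[ConceptMention, ModifierMention]]:
    """Pair each concept with its nearest same-sentence modifier within
    ``max_pair_distance`` tokens; ties prefer a preceding modifier, then
    the leftmost. Concepts with no eligible modifier yield no pair."""
    pairs = []
    for c in concepts:
        best = None
        for m in modifiers:
            if m.sentence_index != c.sentence_index:
                continue
            gap = _gap_tokens(tokens, (c.start, c.end), (m.start, m.end))
            if gap > max_pair_distance:
                continue
            precedes = 0 if m.start <= c.start else 1
            key = (gap, precedes, m.start)
            if best is None or key < best[0]:
                best = (key, m)
        if best is not None:
            pairs.append((c, best[1]))
    return pairs


def _cue_matches(
    text: str, sentence: Sentence, patterns: Sequence[str], pseudo_spans: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for s, e in _find_matches(text[sentence.start : sentence.end], patterns):
        s, e = s + sentence.start, e + sentence.start
        if any(s >= ps and e <= pe for ps, pe in pseudo_spans):
            continue
        out.append((s, e))
    return out


def assign_polarity(
    concept: ConceptMention,
    text: str,
    tokens: list[Token],
    sentences: list[Sentence],
    lexicon: Lexicon,
    negation_scope: int = 6,
) -> str:
    """ConText-style negation: NEGATED iff a (non-pseudo) pre-scope cue
    precedes the concept within ``negation_scope`` tokens in the same
    sentence with no termination cue in between; post-scope cues mirror
    this forward."""
    sent = sentences[concept.sentence_index]
    sent_text = text[sent.start : sent.end]
    pseudo = [
        (s + sent.start, e + sent.start)
        for s, e in _find_matches(sent_text, lexicon.pseudo_negation_cues)
    ]
    terms = [
        (s + sent.start, e + sent.start)
        for s, e in _find_matches(sent_text, lexicon.termination_cues)
    ]
    for s, e in _cue_matches(text, sent, lexicon.negation_cues["pre"], pseudo):
        if e > concept.start:
            continue
        if _gap_tokens(tokens, (s, e), (concept.start, concept.end)) > negation_scope:
            continue
        if any(ts >= e and te <= concept.start for ts, te in terms):
            continue
        return NEGATED
    for s, e in _cue_matches(text, sent, lexicon.negation_cues["post"], pseudo):
        if s < concept.end:
            continue
        if _gap_tokens(tokens, (concept.start, concept.end), (s, e)) > negation_scope:
            continue
        if any(ts >= concept.end and te <= s for ts, te in terms):
            continue
        return NEGATED
    return AFFIRMED


def attribute_scope(
    concept: ConceptMention,
    modifier: Optional[ModifierMention],
    text: str,
    tokens: list[Token],
    sentences: list[Sentence],
    lexicon: Lexicon,
    family_proximity: int = 5,
) -> str:
    """FAMILY iff a kinship term lies within ``family_proximity`` tokens
    of the concept-modifier span (either side, same sentence)."""
    span = (concept.start, concept.end)
    if modifier is not None and modifier.sentence_index == concept.sentence_index:
        span = (min(span[0], modifier.start), max(span[1], modifier.end))
    sent = sentences[concept.sentence_index]
    for s, e in _find_matches(text[sent.start : sent.end], lexicon.family_terms):
        s, e = s + sent.start, e + sent.start
        if _gap_tokens(tokens, span, (s, e)) <= family_proximity:
            return FAMILY
    return PERSONAL


def _is_intrinsic_past(concept: ConceptMention, lexicon: Lexicon) -> bool:
    return any(
        compile_pattern(p).fullmatch(concept.matched_text)
        for p in lexicon.intrinsic_past_concepts
    )


def extract_instances(
    text: str, lexicon: Lexicon, config: ExtractorConfig | None = None
) -> list[HistoryInstance]:
    """Run the full rule pipeline on one note.

    Deterministic for fixed inputs; output sorted by concept start
    offset (ties: end offset, then category name).
    """
    config = config or ExtractorConfig()
    tokens = tokenize(text)
    if not tokens:
        return []
    sentences = segment_sentences(text, tokens)
    concepts = find_concept_mentions(text, tokens, sentences, lexicon)
    modifiers = find_history_modifiers(
        text, tokens, sentences, lexicon, include_temporal=config.enable_temporal_modifiers
    )
    pairs = pair_concept_modifier(concepts, modifiers, tokens, config.max_pair_distance)
    paired = {id(c) for c, _ in pairs}

    instances: list[HistoryInstance] = []
    for c, m in pairs:
        polarity = assign_polarity(c, text, tokens, sentences, lexicon, config.negation_scope)
        scope = attribute_scope(c, m, text, tokens, sentences, lexicon, config.family_proximity)
        instances.append(HistoryInstance(concept=c, modifier=m, polarity=polarity, scope=scope))

    for c in concepts:
        if id(c) in paired:
            continue
        polarity = assign_polarity(c, text, tokens, sentences, lexicon, config.negation_scope)
        scope = attribute_scope(c, None, text, tokens, sentences, lexicon, config.family_proximity)
        if config.relaxed_family_events and scope == FAMILY and _is_intrinsic_past(c, lexicon):
            instances.append(HistoryInstance(concept=c, modifier=None, polarity=polarity, scope=scope))
        elif config.treat_negated_unmodified_as_history and polarity == NEGATED:
            instances.append(HistoryInstance(concept=c, modifier=None, polarity=polarity, scope=scope))

    instances.sort(key=HistoryInstance.sort_key)
    return instances


def instances_to_jsonl(note_id: str, instances: Iterable[HistoryInstance]) -> str:
    """Serialize instances as JSON lines (one instance per line)."""
    return "".join(
        json.dumps(inst.to_record(note_id), sort_keys=True) + "\n" for inst in instances
    )
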