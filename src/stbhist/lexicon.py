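"""Lexicon management, clinical tokenization, and sentence segmentation.

The extractor uses a dual-lexicon design: *target concepts* — surface
forms of suicidal thoughts and behaviors (STB), split into suicidal
ideation (SI), suicidal behavior (SB), and suicide attempt (SA) — and
*historical modifiers* that mark a mention as referring to the past
("history of", "h/o", "prior", or a bare year/date). Around these sit
the ConText-style machinery (negation cues, pseudo-negation cues,
scope-terminating tokens), kinship terms for family attribution, and an
exclusion list of phrases that must never count as a target concept
(non-life-threatening behaviors such as cutting or burning, and
safety-planning boilerplate).

All patterns are regular expressions matched case-insensitively with
word boundaries; a literal space in a pattern matches any whitespace
run. Character offsets are 0-based half-open throughout the package.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

CATEGORIES: tuple[str, ...] = ("SI", "SB", "SA")

#: Clinical abbreviations with internal punctuation kept as one token.
CLINICAL_ABBREVIATIONS: tuple[str, ...] = ("h/o", "s/p", "c/o", "w/o")

_TOKEN_RE = re.compile(
    r"(?<!\w)(?:" + "|".join(re.escape(a) for a in CLINICAL_ABBREVIATIONS) + r")(?!\w)"
    r"|[A-Za-z0-9]+"
    r"|[^\sA-Za-z0-9]",
    re.IGNORECASE,
)


class LexiconError(ValueError):
    """Raised when a lexicon file fails schema or invariant validation."""


@dataclass(frozen=True)
class Token:
    """One token with 0-based half-open character offsets into the note."""

    text: str
    start: int
    end: int
    index: int


@dataclass(frozen=True)
class Sentence:
    """A sentence span: character offsets plus first/last token indices."""

    start: int
    end: int
    first_token: int
    last_token: int


_LIST_FIELDS = (
    "history_modifiers",
    "temporal_modifiers",
    "family_terms",
    "pseudo_negation_cues",
    "termination_cues",
    "exclusions",
    "intrinsic_past_concepts",
)

# temporal_modifiers and intrinsic_past_concepts are extensions that may
# legitimately be emptied (e.g. to disable year-pattern modifiers).
_MAY_BE_EMPTY = ("temporal_modifiers", "intrinsic_past_concepts")


@dataclass
class Lexicon:
    """Validated pattern collections driving every extraction stage."""

    target_concepts: dict[str, list[str]]
    history_modifiers: list[str]
    family_terms: list[str]
    negation_cues: dict[str, list[str]]  # keys: "pre", "post"
    pseudo_negation_cues: list[str]
    termination_cues: list[str]
    exclusions: list[str]
    temporal_modifiers: list[str] = field(default_factory=list)
    intrinsic_past_concepts: list[str] = field(default_factory=list)
    lexicon_version: str = "0"

    def validate(self) -> None:
        for cat in CATEGORIES:
            pats = self.target_concepts.get(cat)
            if not pats:
                raise LexiconError(f"target_concepts[{cat}] is empty or missing")
        unknown = set(self.target_concepts) - set(CATEGORIES)
        if unknown:
            raise LexiconError(f"unknown concept categories: {sorted(unknown)}")
        for name in _LIST_FIELDS:
            pats = getattr(self, name)
            if not pats and name not in _MAY_BE_EMPTY:
                raise LexiconError(f"{name} is empty")
        for side in ("pre", "post"):
            if not self.negation_cues.get(side):
                raise LexiconError(f"negation_cues[{side}] is empty or missing")
        for name, pats in self._all_pattern_lists():
            for pat in pats:
                if not isinstance(pat, str) or not pat:
                    raise LexiconError(f"{name} contains an empty or non-string pattern")
                try:
                    compile_pattern(pat)
                except re.error as exc:
                    raise LexiconError(f"{name} pattern {pat!r} does not compile: {exc}") from exc
        targets = {p.lower() for pats in self.target_concepts.values() for p in pats}
        clash = targets & {e.lower() for e in self.exclusions}
        if clash:
            raise LexiconError(f"exclusions overlap target_concepts: {sorted(clash)}")

    def _all_pattern_lists(self) -> Iterable[tuple[str, list[str]]]:
        for cat, pats in self.target_concepts.items():
            yield f"target_concepts[{cat}]", pats
        for name in _LIST_FIELDS:
            yield name, getattr(self, name)
        for side, pats in self.negation_cues.items():
            yield f"negation_cues[{side}]", pats

    def to_dict(self) -> dict:
        return {
            "lexicon_version": self.lexicon_version,
            "target_concepts": {c: list(p) for c, p in self.target_concepts.items()},
            "history_modifiers": list(self.history_modifiers),
            "temporal_modifiers": list(self.temporal_modifiers),
            "family_terms": list(self.family_terms),
            "negation_cues": {s: list(p) for s, p in self.negation_cues.items()},
            "pseudo_negation_cues": list(self.pseudo_negation_cues),
            "termination_cues": list(self.termination_cues),
            "exclusions": list(self.exclusions),
            "intrinsic_past_concepts": list(self.intrinsic_past_concepts),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Lexicon":
        if not isinstance(data, Mapping):
            raise LexiconError("lexicon file must contain a mapping at top level")
        known = {
            "lexicon_version",
            "target_concepts",
            "negation_cues",
            *_LIST_FIELDS,
            "family_terms",
        }
        unknown = set(data) - known
        if unknown:
            raise LexiconError(f"unknown lexicon fields: {sorted(unknown)}")
        try:
            lex = cls(
                target_concepts={c: list(p) for c, p in dict(data["target_concepts"]).items()},
                history_modifiers=list(data["history_modifiers"]),
                family_terms=list(data["family_terms"]),
                negation_cues={s: list(p) for s, p in dict(data["negation_cues"]).items()},
                pseudo_negation_cues=list(data["pseudo_negation_cues"]),
                termination_cues=list(data["termination_cues"]),
                exclusions=list(data["exclusions"]),
                temporal_modifiers=list(data.get("temporal_modifiers", [])),
                intrinsic_past_concepts=list(data.get("intrinsic_past_concepts", [])),
                lexicon_version=str(data.get("lexicon_version", "0")),
            )
        except (KeyError, TypeError, AttributeError) as exc:
            raise LexiconError(f"malformed lexicon field: {exc}") from exc
        lex.validate()
        return lex


@lru_cache(maxsize=4096)
def compile_pattern(pattern: str) -> re.Pattern:
    """Compile one lexicon pattern: case-insensitive, word-bounded,
    literal spaces made whitespace-tolerant."""
    body = pattern.replace(" ", r"\s+")
    return re.compile(rf"(?<!\w)(?:{body})(?!\w)", re.IGNORECASE)


def load_lexicon(source: str | Path | None = None) -> Lexicon:
    """Load and validate a lexicon from a YAML/JSON file, or the
    packaged default when *source* is None."""
    if source is None:
        text = resources.files("stbhist.data").joinpath("default_lexicon.yaml").read_text()
    else:
        text = Path(source).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise LexiconError(f"cannot parse lexicon file: {exc}") from exc
    return Lexicon.from_dict(data)


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write a lexicon to YAML (or JSON when the suffix is .json);
    write-then-load round-trips to an identical lexicon."""
    path = Path(path)
    data = lexicon.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False, allow_unicode=True))


def tokenize(text: str) -> list[Token]:
    """Tokenize clinical text.

    Maximal alphanumeric runs and individual punctuation marks become
    tokens; whitelisted clinical abbreviations with internal punctuation
    ("h/o", "s/p", ...) are kept whole. Offsets are faithful:
    ``text[t.start:t.end] == t.text``.
    """
    return [
        Token(text=m.group(0), start=m.start(), end=m.end(), index=i)
        for i, m in enumerate(_TOKEN_RE.finditer(text))
    ]


def _sentence_breaks(text: str) -> list[int]:
    breaks = set()
    for i, ch in enumerate(text):
        if ch == "\n":
            breaks.add(i + 1)
        elif ch in ".!?":
            j = i + 1
            while j < len(text) and text[j] in ".!?":
                j += 1
            k = j
            while k < len(text) and text[k].isspace():
                k += 1
            if k > j and k < len(text) and text[k].isupper():
                breaks.add(j)
    return sorted(breaks)


def segment_sentences(text: str, tokens: list[Token]) -> list[Sentence]:
    """Split *text* into sentences at sentence-final punctuation followed
    by whitespace and a capital, and at newlines.

    Sentences partition the tokenized region: every token belongs to
    exactly one sentence. Spans without tokens are dropped.
    """
    if not tokens:
        return []
    bounds = [0, *_sentence_breaks(text), len(text)]
    sentences: list[Sentence] = []
    ti = 0
    for start, end in zip(bounds, bounds[1:]):
        first = None
        while ti < len(tokens) and tokens[ti].start < end:
            if first is None:
                first = ti
            ti += 1
        if first is not None:
            sentences.append(
                Sentence(start=start, end=end, first_token=first, last_token=ti - 1)
            )
    return sentences


def sentence_index_of(sentences: list[Sentence], offset: int) -> int:
    """Index of the sentence whose character span contains *offset*
    (falls back to the nearest preceding sentence)."""
    idx = 0
    for i, s in enumerate(sentences):
        if s.start <= offset:
            idx = i
        else:
            break
    return idx


def token_range(tokens: list[Token], start: int, end: int) -> tuple[int, int]:
    """(first, last) indices of tokens overlapping character span
    [start, end)."""
    first = last = None
    for t in tokens:
        if t.end > start and t.start < end:
            if first is None:
                first = t.index
            last = t.index
        elif t.start >= end:
            break
    if first is None:
        raise ValueError(f"character span ({start}, {end}) covers no token")
    return first, last
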