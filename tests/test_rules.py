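"""Rule-based extraction: concept/modifier matching, pairing, negation,
family attribution, and full-pipeline determinism."""

import dataclasses
import json

import pytest

from stbhist.lexicon import segment_sentences, tokenize
from stbhist.rules import (
    AFFIRMED,
    FAMILY,
    NEGATED,
    PERSONAL,
    ExtractorConfig,
    assign_polarity,
    attribute_scope,
    extract_instances,
    find_concept_mentions,
    find_history_modifiers,
    instances_to_jsonl,
    pair_concept_modifier,
)


def _prep(text):
    toks = tokenize(text)
    return toks, segment_sentences(text, toks)


class TestConceptMentions:
    @pytest.mark.parametrize(
        "text,n,category",
        [
            ("endorses suicidal ideation", 1, "SI"),
            ("SUICIDE ATTEMPT x2", 1, "SA"),
            ("pt reports cutting behavior", 0, None),
            ("suicide precautions reviewed", 0, None),
        ],
    )
    def test_examples(self, lexicon, text, n, category):
        toks, sents = _prep(text)
        mentions = find_concept_mentions(text, toks, sents, lexicon)
        assert len(mentions) == n
        if n:
            assert mentions[0].category == category
            assert text[mentions[0].start : mentions[0].end] == mentions[0].matched_text

    def test_longest_match_wins_on_overlap(self, lexicon):
        # "si" alone is a target; the full phrase must win.
        text = "active si reported"
        toks, sents = _prep(text)
        mentions = find_concept_mentions(text, toks, sents, lexicon)
        assert [m.matched_text for m in mentions] == ["active si"]

    def test_mentions_sorted_by_start(self, lexicon):
        text = "suicide attempt then later suicidal ideation"
        toks, sents = _prep(text)
        mentions = find_concept_mentions(text, toks, sents, lexicon)
        assert [m.category for m in mentions] == ["SA", "SI"]
        assert mentions[0].start < mentions[1].start


class TestHistoryModifiers:
    @pytest.mark.parametrize(
        "text,expected,kind",
        [
            ("history of SA", "history of", "explicit_history"),
            ("h/o SI", "h/o", "explicit_history"),
            ("suicide attempt in 2014", "in 2014", "temporal"),
            ("Suicidal ideation 03/12/2015", "03/12/2015", "temporal"),
        ],
    )
    def test_found(self, lexicon, text, expected, kind):
        toks, sents = _prep(text)
        mods = find_history_modifiers(text, toks, sents, lexicon)
        assert [(m.matched_text.lower(), m.kind) for m in mods] == [(expected, kind)]

    def test_no_modifier_present(self, lexicon):
        text = "suicidal ideation today"
        toks, sents = _prep(text)
        assert find_history_modifiers(text, toks, sents, lexicon) == []

    def test_temporal_disabled(self, lexicon):
        text = "suicide attempt in 2014"
        toks, sents = _prep(text)
        assert find_history_modifiers(text, toks, sents, lexicon, include_temporal=False) == []


class TestPairing:
    def test_adjacent_pair(self, lexicon):
        text = "history of suicide attempt"
        toks, sents = _prep(text)
        concepts = find_concept_mentions(text, toks, sents, lexicon)
        mods = find_history_modifiers(text, toks, sents, lexicon)
        assert len(pair_concept_modifier(concepts, mods, toks)) == 1

    def test_sentence_bound_blocks_pair(self, lexicon):
        text = "Current suicidal ideation. History of depression."
        toks, sents = _prep(text)
        concepts = find_concept_mentions(text, toks, sents, lexicon)
        mods = find_history_modifiers(text, toks, sents, lexicon)
        assert concepts and mods
        assert pair_concept_modifier(concepts, mods, toks) == []

    def test_nearest_modifier_vs_bruteforce(self, lexicon):
        # two modifiers at different distances; brute-force nearest must agree
        text = "prior course reviewed, then past suicidal ideation"
        toks, sents = _prep(text)
        concepts = find_concept_mentions(text, toks, sents, lexicon)
        mods = find_history_modifiers(text, toks, sents, lexicon)
        assert len(mods) == 2
        pairs = pair_concept_modifier(concepts, mods, toks, max_pair_distance=10)

        def tok_of(start):
            return max(t.index for t in toks if t.start <= start)

        c = concepts[0]
        best = min(
            (m for m in mods),
            key=lambda m: abs(tok_of(c.start) - tok_of(m.start)),
        )
        assert pairs == [(c, best)]
        assert pairs[0][1].matched_text == "past"

    def test_distance_cap(self, lexicon):
        filler = "alpha " * 12
        text = f"history of {filler}suicide attempt"
        toks, sents = _prep(text)
        concepts = find_concept_mentions(text, toks, sents, lexicon)
        mods = find_history_modifiers(text, toks, sents, lexicon)
        assert pair_concept_modifier(concepts, mods, toks, max_pair_distance=10) == []
        assert len(pair_concept_modifier(concepts, mods, toks, max_pair_distance=20)) == 1


class TestPolarity:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("denies any history of suicidal ideation", NEGATED),
            ("history of suicide attempt in 2005", AFFIRMED),
            ("no prior suicide attempt", NEGATED),
            ("no increase in suicidal ideation", AFFIRMED),  # pseudo-negation
        ],
    )
    def test_pre_scope(self, lexicon, text, expected):
        toks, sents = _prep(text)
        c = find_concept_mentions(text, toks, sents, lexicon)[0]
        assert assign_polarity(c, text, toks, sents, lexicon) == expected

    def test_termination_cue_ends_negation_scope(self, lexicon):
        text = "denies SI but endorses prior suicide attempt"
        toks, sents = _prep(text)
        concepts = find_concept_mentions(text, toks, sents, lexicon)
        by_cat = {c.category: c for c in concepts}
        assert assign_polarity(by_cat["SI"], text, toks, sents, lexicon) == NEGATED
        assert assign_polarity(by_cat["SA"], text, toks, sents, lexicon) == AFFIRMED

    def test_post_scope_cue(self, lexicon):
        text = "prior suicidal ideation was ruled out"
        toks, sents = _prep(text)
        c = find_concept_mentions(text, toks, sents, lexicon)[0]
        assert assign_polarity(c, text, toks, sents, lexicon) == NEGATED

    def test_scope_window_limit(self, lexicon):
        filler = "word " * 8
        text = f"denies {filler}history of suicidal ideation"
        toks, sents = _prep(text)
        c = find_concept_mentions(text, toks, sents, lexicon)[0]
        assert assign_polarity(c, text, toks, sents, lexicon, negation_scope=6) == AFFIRMED


class TestScope:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("father with history of suicide attempt", FAMILY),
            ("history of suicide attempt", PERSONAL),
        ],
    )
    def test_examples(self, lexicon, text, expected):
        toks, sents = _prep(text)
        c = find_concept_mentions(text, toks, sents, lexicon)[0]
        mods = find_history_modifiers(text, toks, sents, lexicon)
        m = mods[0] if mods else None
        assert attribute_scope(c, m, text, toks, sents, lexicon) == expected

    def test_proximity_limit_forces_personal(self, lexicon):
        gap = "alpha " * 20
        text = f"mother mentioned. {gap}history of suicide attempt"
        toks, sents = _prep(text)
        c = find_concept_mentions(text, toks, sents, lexicon)[0]
        m = find_history_modifiers(text, toks, sents, lexicon)[0]
        assert attribute_scope(c, m, text, toks, sents, lexicon, family_proximity=5) == PERSONAL


class TestExtractInstances:
    def test_empty_note(self, lexicon, extractor_config):
        assert extract_instances("", lexicon, extractor_config) == []

    def test_exclusion_phrase_yields_nothing(self, lexicon, extractor_config):
        assert extract_instances("suicide precautions reviewed", lexicon, extractor_config) == []

    def test_mixed_note_default_config(self, lexicon, extractor_config):
        text = "Pt denies SI. Mother has a history of suicide attempt."
        inst = extract_instances(text, lexicon, extractor_config)
        # default config: bare negated "SI" without modifier is not a history instance
        assert [(i.polarity, i.scope) for i in inst] == [(AFFIRMED, FAMILY)]

    def test_mixed_note_with_negated_unmodified_flag(self, lexicon):
        config = ExtractorConfig(treat_negated_unmodified_as_history=True)
        text = "Pt denies SI. Mother has a history of suicide attempt."
        inst = extract_instances(text, lexicon, config)
        assert [(i.polarity, i.scope) for i in inst] == [
            (NEGATED, PERSONAL),
            (AFFIRMED, FAMILY),
        ]

    def test_relaxed_family_event_without_modifier(self, lexicon):
        text = "Her father committed suicide."
        inst = extract_instances(text, lexicon, ExtractorConfig(enable_temporal_modifiers=False))
        assert [(i.polarity, i.scope, i.concept.category) for i in inst] == [
            (AFFIRMED, FAMILY, "SA")
        ]
        off = extract_instances(
            text, lexicon,
            ExtractorConfig(enable_temporal_modifiers=False, relaxed_family_events=False),
        )
        assert off == []

    def test_sorted_by_anchor_offset(self, lexicon, extractor_config):
        text = "Past suicide attempt. Denies prior suicidal ideation."
        inst = extract_instances(text, lexicon, extractor_config)
        assert len(inst) == 2
        assert inst[0].anchor_offset < inst[1].anchor_offset

    def test_determinism_byte_for_byte(self, lexicon, extractor_config, small_bundle):
        for note in small_bundle.notes[:30]:
            a = instances_to_jsonl(note.note_id, extract_instances(note.text, lexicon, extractor_config))
            b = instances_to_jsonl(note.note_id, extract_instances(note.text, lexicon, extractor_config))
            assert a == b

    def test_offset_integrity_on_synthetic_notes(self, lexicon, extractor_config, small_bundle):
        for note in small_bundle.notes:
            for i in extract_instances(note.text, lexicon, extractor_config):
                assert note.text[i.concept.start : i.concept.end] == i.concept.matched_text

    def test_monotone_under_exclusion(self, lexicon, extractor_config, small_bundle):
        import yaml
        from stbhist.lexicon import Lexicon

        data = lexicon.to_dict()
        data["target_concepts"] = {
            c: [p for p in pats if p != "suicide attempts?"]
            for c, pats in data["target_concepts"].items()
        }
        data["exclusions"].append("suicide attempt")
        stricter = Lexicon.from_dict(data)
        for note in small_bundle.notes[:40]:
            before = len(extract_instances(note.text, lexicon, extractor_config))
            after = len(extract_instances(note.text, stricter, extractor_config))
            assert after <= before

    def test_instance_level_agreement_with_planted_gold(
        self, lexicon, extractor_config, small_bundle
    ):
        """Noise-free corpus: extraction recovers exactly the planted
        instances (category, polarity, scope, offsets)."""
        for note, gold in zip(small_bundle.notes, small_bundle.gold):
            got = {
                (i.concept.category, i.polarity, i.scope, i.concept.start, i.concept.end)
                for i in extract_instances(note.text, lexicon, extractor_config)
            }
            want = {
                (p.category, p.polarity, p.scope, p.start, p.end) for p in gold.instances
            }
            assert got == want, note.note_id
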