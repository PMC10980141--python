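# Default lexicon for the suicide-history extractor.
#
# This is a curated reconstruction: the categories below (target STB
# concepts, historical modifiers, family terms, ConText-style cue sets,
# exclusions) follow the published dual-lexicon design, but the original
# institutional term lists are not public, so the entries here were
# assembled from the phrases the literature names plus common clinical
# shorthand. Every category can be overridden from a user file with the
# same schema.
#
# Patterns are regular expressions matched case-insensitively with word
# boundaries; a literal space matches any whitespace run.

lexicon_version: "1.0"

target_concepts:
  SI:
    - suicidal ideation
    - suicidal ideations
    - suicidal thoughts
    - suicidal thinking
    - suicidal intent
    - thoughts of suicide
    - thoughts of killing (?:him|her|them)self
    - active si
    - passive si
    - si
  SB:
    - suicidal behaviors?
    - suicidal behaviours?
    - suicidal gestures?
    - suicide gestures?
    - suicidal acts?
    - self-directed violence
  SA:
    - suicide attempts?
    - attempted suicide
    - attempt at suicide
    - tried to kill (?:him|her|them)self
    - overdosed? with intent to die
    - committed suicide
    - died by suicide
    - completed suicide

history_modifiers:
  - history of
  - hx of
  - h/o
  - hx
  - prior
  - past
  - previous
  - previously
  - remote
  - in the past
  - years ago

# Year/date expressions that mark an event as historical ("suicide
# attempt in 2014", "Suicidal ideation 03/12/2015"). Shipped on by
# default as a remediation for timestamp-style documentation, which is a
# known false-negative mode of history extraction; can be disabled via
# ExtractorConfig.enable_temporal_modifiers.
temporal_modifiers:
  - '(?:in|on|around|since) (?:19|20)\d{2}'
  - '(?:19|20)\d{2}'
  - '\d{1,2}/\d{1,2}/(?:\d{4}|\d{2})'

family_terms:
  - mother
  - father
  - mom
  - dad
  - brother
  - sister
  - sibling
  - grandmother
  - grandfather
  - grandparent
  - aunt
  - uncle
  - cousin
  - son
  - daughter
  - family
  - relative
  - maternal
  - paternal

negation_cues:
  pre:
    - "no"
    - denies
    - denied
    - denying
    - without
    - negative for
    - never
    - ruled out
    - absence of
    - no evidence of
    - does not endorse
    - did not have
    - "not"
  post:
    - was ruled out
    - is denied
    - was denied
    - not present
    - unlikely

pseudo_negation_cues:
  - no increase in
  - no change in
  - no further increase in
  - not only
  - without difficulty

termination_cues:
  - but
  - however
  - although
  - though
  - except
  - aside from
  - apart from
  - ;

# Phrases never matched as target concepts: non-life-threatening
# behaviors and safety-planning boilerplate that merely contains the
# string "suicide".
exclusions:
  - cutting
  - burning
  - suicide precautions
  - suicide prevention
  - suicide hotline
  - suicide risk assessment
  - suicide risk screening
  - suicide safety plan

# Concepts that carry intrinsic pastness (completed-suicide events);
# when a family term is nearby these may form a family-history instance
# without an explicit historical modifier.
intrinsic_past_concepts:
  - committed suicide
  - died by suicide
  - completed suicide
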