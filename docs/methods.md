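# Methods

This note documents the models and procedures `stbhist` implements, the
parameters that matter, the synthetic data that stands in for protected
clinical corpora, and the design choices made where the design was
genuinely open.

## Task

Given a clinical note, decide two binary outcomes: does the note
document a **personal history** of suicidal thoughts and behaviors
(PSH), and a **family history** (FSH)? STB covers suicidal ideation
(SI), suicidal behavior (SB), and suicide attempt (SA); extraction
keeps the category, classification collapses the three into one
history outcome per scope. Patient-level labels are the any-positive
roll-up over a patient's notes.

## Rule-based extraction

The extractor is a deterministic composition of five stages over a
validated lexicon (`stbhist/data/default_lexicon.yaml`; every category
overridable from file):

1. **Concept matching.** Target-concept patterns are regexes matched
   case-insensitively with word boundaries; literal spaces match any
   whitespace. Candidates overlapping an exclusion phrase are dropped;
   remaining overlaps are resolved longest-match-first, ties to the
   leftmost start. Case-insensitivity is deliberate: notes mix
   "suicide attempt" and "SUICIDE ATTEMPT".
2. **Modifier matching.** Explicit historical phrases ("history of",
   "h/o", "prior", …) plus, by default, *temporal* modifiers — bare
   year/date expressions ("in 2014", "03/12/2015"). Date-only
   ("timestamp-style") documentation is a known false-negative mode of
   modifier-based history extraction, so the temporal patterns ship
   enabled and can be switched off
   (`ExtractorConfig.enable_temporal_modifiers=False`) to reproduce
   the failure.
3. **Pairing.** Each concept pairs with its nearest same-sentence
   modifier within `max_pair_distance` tokens (default 10; ties prefer
   a preceding modifier). A concept with no eligible modifier yields no
   history instance: a bare present-tense "suicidal ideation" is a
   current mention, not history.
4. **Polarity (ConText-style).** NEGATED iff a pre-scope cue
   ("denies", "no", …) precedes the concept within `negation_scope`
   tokens (default 6) in the same sentence with no termination cue
   ("but", "however", ";") in between; post-scope cues ("was ruled
   out") mirror this forward. Cues inside pseudo-negation phrases ("no
   increase in") are ignored. The concept anchors the scope check; the
   distances are counted over all tokens, punctuation included.
5. **Scope.** FAMILY iff a kinship term lies within `family_proximity`
   tokens (default 5, same sentence) of the concept–modifier span;
   else PERSONAL.

The three distances follow common ConText practice; the sources that
motivate this design name the mechanisms but not the values, so all
three are surfaced in `ExtractorConfig`.

Two documented relaxations, both configurable:

* `relaxed_family_events` (default on): intrinsically past concepts
  ("committed suicide", "died by suicide") near a kinship term form a
  family instance without a modifier — family suicide events are
  routinely documented without one ("her father committed suicide").
* `treat_negated_unmodified_as_history` (default off): count a bare
  negated concept ("denies SI") as a NEGATED history instance, for
  annotation schemes that read such denials as history statements.

Tokenization emits maximal alphanumeric runs and single punctuation
marks, keeping whitelisted clinical abbreviations (h/o, s/p, c/o, w/o)
whole; offsets are 0-based half-open and faithful. Sentences split at
sentence-final punctuation followed by whitespace and a capital, and at
newlines. Templated/semi-structured content is processed as plain text
— no template stripping in v1, a known limitation of this class of
tool.

## Document classification

Per scope: no instance → NEGATIVE; one instance → POSITIVE iff
affirmed; several → POSITIVE iff affirmed instances outnumber negated;
a tie takes the polarity of the last-mentioned instance.
"Last-mentioned" is operationalized as the greatest concept start
offset. NEGATIVE deliberately conflates "explicitly negated" and "no
mention" (the binary form matches the four-label note annotation
scheme); a three-way POSITIVE/NEGATED/NO_MENTION view exists for error
analysis.

## Context-window classifier

Anchors are the same STB concept dictionary the rule engine uses (the
concept is the information-bearing n-gram; its historical and negation
context is exactly what the window is meant to capture). For each
anchor, *n* words left and right are extracted — *n* counts word
tokens only, punctuation riding along in the rendered text — windows
cross sentence boundaries, truncate at document edges, merge when
overlapping or adjacent, and join with a reserved `[SEP]` token.
Anchor-free documents keep a reserved `[NO_ANCHOR]` placeholder so
every labelled document enters training and evaluation; a drop-mode is
a one-line filter away. The sweep n ∈ {8, 16, 24, 32} is exposed in
the CLI (`--window-sweep`).

Cross-validation is **repeated random sub-sampling**: each of the 10
folds draws a fresh random 80/20 partition. (A "10-fold CV with 80/20
splits" is internally inconsistent with standard disjoint 10-fold,
which implies 90/10; the repeated-subsampling reading is implemented as
the default and conventional disjoint folds sit behind
`mode="disjoint"`.) Fold metrics are summarised as mean ± sample sd
(n−1). The weighted (support-weighted) average is the headline because
PSH/FSH corpora are unbalanced.

The reference backend is a regularised logistic classifier over token
counts — deterministic given the seed, desk-scale, and sufficient to
exercise the harness. The fine-tuning configuration (batch 16, lr
1e-5, dropout 0.3, cross-entropy, AdamW, 5 epochs, early layers
frozen) is carried in `TrainConfig` for backends that honour it; the
`TransformerBackend` stub defines the contract (including the open
`n_trainable_layers` choice) but GPU-scale fine-tuning is out of scope
here.

## Metrics and ICD baseline

Precision, recall and F1 are computed from per-class confusion counts
with the 0-when-undefined convention (reports carry a
`zero_division_hit` flag); macro is the unweighted two-class mean —
the negative class is included — and weighted is the support-weighted
mean. Cohen's κ uses the marginal-product expected agreement. Tests
cross-check both against scikit-learn.

The ICD baseline counts gold-positive patients with at least one
qualifying code dated **on or before** (inclusive) the patient's index
date, defined as the earliest analyzed note date. The shipped code set
(`stbhist/data/icd_codes.yaml`) is an editable reconstruction: ICD-10
R45.851, T14.91, X71–X83, Z91.5; ICD-9 V62.84, E950–E959. Codes match
by prefix after dot removal; ranges match on the three-character
category.

## Synthetic corpus

The generator emulates the documentation phenomena the pipeline must
handle: explicit affirmed history, negated history, family history
(including modifier-free "father committed suicide" events),
timestamp-style date-only mentions, and distractor boilerplate that
contains the string "suicide" without documenting history. Notes are
filler sentences with planted template sentences inserted; every
planted mention records its surface offsets and template family, so
instance-level and per-failure-mode recall are computable. Note labels
are re-derived from planted instances with the document rule itself,
so generator and classifier cannot drift apart; ICD codes are planted
for truly PSH-positive patients with probability `icd_coding_rate`,
always dated before the first note.

Default conditions: 200 patients, 1–3 notes each, PSH prevalence 0.30
and FSH prevalence 0.10 at patient level (typical of
suicide-string-enriched review corpora), negation rate 0.3,
multi-instance rate 0.2, distractor rate 0.3, ICD coding rate 0.1,
timestamp-style rate 0 unless the failure mode is being studied.
Timestamp-style phrasing applies to a note's primary affirmed mention;
secondary mentions stay explicit, so the failure mode erodes recall
while leaving precision measurable rather than undefined.

What passing on this corpus shows — and does not: the pipeline's
mechanics (matching, pairing, negation, scope, aggregation, windows,
CV, baseline arithmetic) are exact on text whose surface forms the
lexicon covers. It does not show robustness to real clinical language:
misspellings, ad-hoc abbreviations, copy-forward templating, and
site-specific phrasing are exactly the variation that degrades
rule-based tools across institutions, and none of it is modelled.

## Numerical and degenerate-input choices

* Character offsets 0-based half-open everywhere; BRAT surfaces are
  validated against text slices on read.
* Overlap resolution (concepts, modifiers, anchors):
  longest-match-wins, ties leftmost, then category name — fully
  deterministic, and instance lists sort by (start, end, category).
* Empty text tokenizes to nothing and classifies NEGATIVE/NEGATIVE;
  empty span-interval lists render the placeholder; single-class
  training folds are skipped with a recorded warning; κ returns 1.0
  when observed and expected agreement are both 1, NaN if expected
  agreement alone is 1.
* Unparseable ICD dates skip the record with a log entry rather than
  aborting a batch run; corpus readers, by contrast, reject malformed
  records outright — annotation inputs must be exact, exposure data
  may be dirty.
* Problem sizes in the test suite and acceptance script (200–500
  synthetic patients, 10 CV folds) were chosen as the smallest corpora
  at which the binomial checks (prevalence, coding-rate) have
  non-trivial power.
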