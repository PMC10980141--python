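# stbhist

Detection of **personal and family history of suicidal thoughts and
behaviors** (PSH / FSH) in free-text clinical notes.

A prior personal or family history of suicidal thoughts and behaviors
(STB — suicidal ideation *SI*, suicidal behavior *SB*, suicide attempt
*SA*) is among the strongest risk factors for future suicide, yet it is
rarely recorded as a structured ICD-9/10 diagnosis: it usually lives
only in narrative notes. `stbhist` is for clinical-NLP researchers and
phenotyping teams who need note-level and patient-level PSH/FSH flags
from EHR text, and a way to quantify how much structured codes miss.

## What it implements

**Rule-based extractor.** A dual-lexicon pipeline: match STB target
concepts (with an exclusion list for non-life-threatening behaviors
such as *cutting* and *burning* and safety-planning boilerplate); match
historical modifiers ("history of", "h/o", "prior", and optionally bare
year/date expressions); pair each concept with its nearest
same-sentence modifier; assign polarity with a ConText-style negation
pass (pre/post cues, pseudo-negation, scope-terminating tokens such as
*but*); attribute PERSONAL vs FAMILY scope by kinship-term proximity.

**Document and patient labels.** For the instances of one scope in a
note: no instance → NEGATIVE; one instance → POSITIVE iff affirmed;
several → majority polarity, ties resolved by the last-mentioned
instance. A patient is POSITIVE iff any note is.

**Context-window classifier path.** Anchor phrases from the same
dictionary are matched per note; windows of *n* words (n ∈ {8, 16, 24,
32}) on each side are extracted, merged, and joined into one labelled
text per document, then classified by a backend under repeated random
80/20 cross-validation (10 folds by default) scored with weighted
precision/recall/F1. A deterministic logistic-regression reference
backend ships with the package; the transformer fine-tuning contract
(batch 16, lr 1e-5, dropout 0.3, 5 epochs, AdamW, early layers frozen)
is exposed for optional GPU backends.

**Evaluation and baseline.** Accuracy, per-class/macro/weighted P/R/F1,
Cohen's κ for annotator agreement, and an ICD-code baseline: the
fraction of gold-positive patients carrying a qualifying STB diagnosis
code on or before the index (earliest note) date, versus the fraction
the NLP detects.

**Synthetic corpus.** Real corpora for this task are protected EHR
data, so a seeded generator produces notes from template families
(affirmed / negated / family / timestamp-style mentions plus
distractors) with instance-level gold offsets, note/patient labels, and
an under-coded ICD table — every result below is computed on it.

## Worked example

```python
from stbhist import load_lexicon, extract_instances, ExtractorConfig, classify_note

lexicon = load_lexicon()
note = ("Patient presents for routine follow up. "
        "Denies current suicidal ideation. "
        "Patient has a history of suicide attempt in 2014.\n"
        "Her father committed suicide in 2001. "
        "Suicide precautions reviewed with patient.")
instances = extract_instances(note, lexicon, ExtractorConfig())
for i in instances:
    print(f"{i.concept.category:3s} {i.polarity:9s} {i.scope:8s} "
          f"{i.concept.matched_text!r} (modifier: {i.modifier.matched_text if i.modifier else None})")
doc = classify_note("note-1", instances)
print(f"PSH = {doc.psh_label}, FSH = {doc.fsh_label}")
```

prints

```
SA  AFFIRMED  PERSONAL 'suicide attempt' (modifier: history of)
SA  AFFIRMED  FAMILY   'committed suicide' (modifier: in 2001)
PSH = POSITIVE, FSH = POSITIVE
```

The explicit "history of suicide attempt" becomes an affirmed personal
instance; "father committed suicide in 2001" is attributed to family
scope; the *current* denied ideation yields no history instance (a
bare present-tense mention has no historical modifier to pair with),
and the safety-planning sentence is suppressed by the exclusion list.
The note is therefore positive for both PSH and FSH.

The same stages are available from the shell:

```bash
stbhist simulate --out bundle --seed 42 --n-patients 200
stbhist extract  --corpus bundle/corpus.jsonl --out instances.jsonl
stbhist classify --corpus bundle/corpus.jsonl --notes-out notes.csv --patients-out patients.csv
stbhist evaluate --gold bundle/gold.csv --pred notes.csv --scope psh
stbhist spans    --corpus bundle/corpus.jsonl --gold bundle/gold.csv --window-sweep --out spans.jsonl
stbhist train    --spans spans_n16.jsonl --folds 10 --seed 3 --out cv.json
stbhist icd-baseline --gold bundle/gold.csv --icd bundle/icd.csv --pred patients.csv
```

## Limitations

The default lexicon is a curated reconstruction, not an institutional
term list; local customization is expected. Semi-structured/templated
note content is processed as plain text. The synthetic corpus exercises
the documented phenomena but does not model real clinical language —
see `docs/methods.md`.
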