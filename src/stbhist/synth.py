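"""Seeded generator of synthetic clinical notes with instance-level
ground truth.

Real corpora for this task are protected EHR data, so every pipeline
stage is exercised on generated notes instead. Each note is assembled
from innocuous clinical filler sentences plus planted mention sentences
drawn from versioned template families:

* ``affirmed_history`` — explicit historical modifier, personal scope
  ("Patient has a history of suicide attempt in 2014.");
* ``negated_history`` — negated personal mention ("No history of
  suicidal ideation.");
* ``timestamp_style`` — affirmed personal mention whose only historical
  marker is a date or year ("Suicidal ideation 03/12/2015."), the
  documentation style known to defeat modifier-based extraction;
* ``family_history`` / ``family_negated`` — kinship-scoped mentions;
* ``distractor`` — safety-planning boilerplate containing the string
  "suicide" but no reportable mention.

Gold note labels are re-derived from the planted instances with the
same single-instance / majority / last-mention rule the document
classifier implements, so generator and classifier cannot drift apart.
An accompanying ICD table codes each truly PSH-positive patient with
probability ``icd_coding_rate``, dated before the earliest note — the
structured-data under-documentation the NLP tools are benchmarked
against.

Timestamp-style phrasing applies to the primary planted mention of a
note; secondary (multi-instance) mentions always use explicit-modifier
templates, so raising ``timestamp_style_rate`` erodes recall without
collapsing precision. No PHI-like strings (names, MRNs) are generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import doclabels
from .corpus_io import BratDocument, BratEntity, Note, write_brat, write_corpus
from .rules import AFFIRMED, FAMILY, NEGATED, PERSONAL, ConceptMention, HistoryInstance


@dataclass
class SyntheticConfig:
    n_patients: int = 200
    notes_per_patient: tuple[int, int] = (1, 3)  # inclusive range
    psh_prevalence: float = 0.3
    fsh_prevalence: float = 0.1
    negation_rate: float = 0.3
    multi_instance_rate: float = 0.2
    timestamp_style_rate: float = 0.0
    distractor_rate: float = 0.3
    icd_coding_rate: float = 0.1
    template_set: str = "v1"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.notes_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("notes_per_patient must be an increasing range with lo >= 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "psh_prevalence", "fsh_prevalence", "negation_rate", "multi_instance_rate",
            "timestamp_style_rate", "distractor_rate", "icd_coding_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class PlantedInstance:
    """One planted mention with its surface offsets and template family."""

    note_id: str
    category: str
    polarity: str
    scope: str
    start: int
    end: int
    surface: str
    family: str


@dataclass
class GoldRecord:
    note_id: str
    patient_id: str
    date: str
    psh_label: str
    fsh_label: str
    instances: list[PlantedInstance] = field(default_factory=list)


@dataclass
class CorpusBundle:
    notes: list[Note]
    gold: list[GoldRecord]
    icd: pd.DataFrame
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# Template bank (v1)

@dataclass(frozen=True)
class Template:
    family: str
    text: str  # may contain {concept}, {year}, {date}
    polarity: str | None = None
    scope: str | None = None
    categories: tuple[str, ...] = ("SI", "SA", "SB")


CONCEPT_SURFACES: dict[str, tuple[str, ...]] = {
    "SI": ("suicidal ideation", "suicidal thoughts", "thoughts of suicide"),
    "SB": ("suicidal behavior",),
    "SA": ("suicide attempt", "attempted suicide"),
}

TEMPLATES_V1: dict[str, tuple[Template, ...]] = {
    "affirmed_history": (
        Template("affirmed_history", "Patient has a history of {concept} in {year}.", AFFIRMED, PERSONAL),
        Template("affirmed_history", "Reports prior {concept} several years ago.", AFFIRMED, PERSONAL),
        Template("affirmed_history", "Past {concept} noted during intake.", AFFIRMED, PERSONAL),
        Template("affirmed_history", "H/o {concept} documented in outside records.", AFFIRMED, PERSONAL),
    ),
    "timestamp_style": (
        Template("timestamp_style", "{concept} {date}.", AFFIRMED, PERSONAL),
        Template("timestamp_style", "{concept} in {year} requiring brief hospitalization.", AFFIRMED, PERSONAL),
        Template("timestamp_style", "Hospitalized for {concept} in {year}.", AFFIRMED, PERSONAL),
    ),
    "negated_history": (
        Template("negated_history", "Patient denies any prior {concept}.", NEGATED, PERSONAL),
        Template("negated_history", "No history of {concept}.", NEGATED, PERSONAL),
        Template("negated_history", "No prior {concept} reported.", NEGATED, PERSONAL),
        Template("negated_history", "Denies past {concept} or self-harm.", NEGATED, PERSONAL),
    ),
    "family_history": (
        Template("family_history", "Patient's mother has a history of {concept}.", AFFIRMED, FAMILY),
        Template("family_history", "Family history of {concept} in father.", AFFIRMED, FAMILY),
        Template("family_history", "Brother with history of {concept}.", AFFIRMED, FAMILY),
        Template("family_history", "Her father committed suicide in {year}.", AFFIRMED, FAMILY, ("SA",)),
    ),
    "family_negated": (
        Template("family_negated", "No family history of {concept}.", NEGATED, FAMILY),
        Template("family_negated", "Denies family history of {concept}.", NEGATED, FAMILY),
    ),
    "distractor": (
        Template("distractor", "Suicide precautions reviewed with patient."),
        Template("distractor", "Provided the national suicide prevention lifeline number."),
        Template("distractor", "Suicide risk screening completed per clinic policy."),
    ),
}

FILLER_SENTENCES: tuple[str, ...] = (
    "Patient presents for routine follow up.",
    "Medications were reviewed and reconciled.",
    "Vital signs stable; blood pressure 128/76.",
    "Sleep quality has improved with current regimen.",
    "Reviewed diet and exercise recommendations.",
    "Labs ordered and pending at this time.",
    "Patient tolerating medication without side effects.",
    "Will follow up in clinic in three months.",
    "Discussed smoking cessation resources.",
    "Gait steady; no assistive device needed.",
)

_INTRINSIC_SA = ("committed suicide", "died by suicide", "completed suicide")


def _realize(template: Template, rng: np.random.Generator) -> tuple[str, int, int, str, str]:
    """Fill a template's slots; returns (sentence, concept_start,
    concept_end, surface, category) with offsets relative to the
    sentence (start == end == -1 for concept-free templates)."""
    text = template.text
    if "{year}" in text:
        text = text.replace("{year}", str(int(rng.integers(1995, 2017))))
    if "{date}" in text:
        m, d, y = int(rng.integers(1, 13)), int(rng.integers(1, 29)), int(rng.integers(1998, 2017))
        text = text.replace("{date}", f"{m:02d}/{d:02d}/{y}")
    fixed = next((p for p in _INTRINSIC_SA if p in text), None)
    if fixed is not None:
        start = text.find(fixed)
        return text, start, start + len(fixed), fixed, "SA"
    idx = text.find("{concept}")
    if idx == -1:
        return text, -1, -1, "", ""
    category = str(rng.choice(template.categories))
    surfaces = CONCEPT_SURFACES[category]
    surface = str(surfaces[int(rng.integers(len(surfaces)))])
    if idx == 0:
        surface = surface[0].upper() + surface[1:]
    sentence = text[:idx] + surface + text[idx + len("{concept}"):]
    return sentence, idx, idx + len(surface), surface, category


def _pick(templates: Sequence[Template], rng: np.random.Generator) -> Template:
    return templates[int(rng.integers(len(templates)))]


def generate_note(
    note_id: str,
    plant_families: Sequence[str],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[str, list[PlantedInstance]]:
    """Assemble one note: filler (plus optional distractor) sentences
    with the requested planted-template sentences inserted in order."""
    bank = TEMPLATES_V1
    k = int(rng.integers(3, 7))
    filler_idx = rng.choice(len(FILLER_SENTENCES), size=k, replace=False)
    background = [FILLER_SENTENCES[i] for i in filler_idx]
    if rng.random() < config.distractor_rate:
        pos = int(rng.integers(len(background) + 1))
        background.insert(pos, _realize(_pick(bank["distractor"], rng), rng)[0])

    planted = []
    for f in plant_families:
        tpl = _pick(bank[f], rng)
        planted.append(_realize(tpl, rng) + (tpl,))
    slots = sorted(int(rng.integers(len(background) + 1)) for _ in planted)
    sentences: list[tuple[str, tuple | None]] = [(s, None) for s in background]
    for offset, (slot, p) in enumerate(zip(slots, planted)):
        sentences.insert(slot + offset, (p[0], p))

    text_parts: list[str] = []
    pos = 0
    instances: list[PlantedInstance] = []
    for i, (sent, p) in enumerate(sentences):
        if i > 0:
            sep = "\n" if rng.random() < 0.25 else " "
            text_parts.append(sep)
            pos += len(sep)
        if p is not None and p[1] >= 0:
            _, cstart, cend, surface, category, tpl = p
            instances.append(
                PlantedInstance(
                    note_id=note_id,
                    category=category,
                    polarity=tpl.polarity or AFFIRMED,
                    scope=tpl.scope or PERSONAL,
                    start=pos + cstart,
                    end=pos + cend,
                    surface=surface,
                    family=tpl.family,
                )
            )
        text_parts.append(sent)
        pos += len(sent)
    return "".join(text_parts), instances


def _note_labels(instances: Sequence[PlantedInstance]) -> tuple[str, str]:
    """Re-derive the note's PSH/FSH labels from planted instances via
    the document classification rule."""
    as_history = [
        HistoryInstance(
            concept=ConceptMention(
                category=p.category, start=p.start, end=p.end,
                matched_text=p.surface, sentence_index=0,
            ),
            modifier=None,
            polarity=p.polarity,
            scope=p.scope,
        )
        for p in instances
    ]
    doc = doclabels.classify_note("_", as_history)
    return doc.psh_label, doc.fsh_label


def generate_corpus(config: SyntheticConfig) -> CorpusBundle:
    """Generate the full bundle: notes, gold records with planted
    instances, and the ICD table. Byte-identical for a fixed config."""
    rng = np.random.default_rng(config.seed)
    notes: list[Note] = []
    gold: list[GoldRecord] = []
    icd_rows: list[dict] = []
    stb_codes = ("R45.851", "T14.91", "X78.8XXA", "E950.9", "V62.84", "Z91.5")
    other_codes = ("I10", "E11.9", "J45.909", "M54.5")
    base = date(2018, 1, 1)

    for p in range(config.n_patients):
        pid = f"P{p:04d}"
        psh_pos = rng.random() < config.psh_prevalence
        fsh_pos = rng.random() < config.fsh_prevalence
        lo, hi = config.notes_per_patient
        n_notes = int(rng.integers(lo, hi + 1))
        day_offsets = sorted(int(rng.integers(0, 365)) for _ in range(n_notes))

        psh_note = int(rng.integers(n_notes)) if psh_pos else -1
        fsh_note = int(rng.integers(n_notes)) if fsh_pos else -1
        neg_note = -1
        if not psh_pos and rng.random() < config.negation_rate:
            neg_note = int(rng.integers(n_notes))
        fneg_note = -1
        if not fsh_pos and rng.random() < config.negation_rate:
            fneg_note = int(rng.integers(n_notes))

        for j in range(n_notes):
            note_id = f"{pid}-N{j}"
            families: list[str] = []
            if j == psh_note:
                primary = (
                    "timestamp_style"
                    if rng.random() < config.timestamp_style_rate
                    else "affirmed_history"
                )
                if rng.random() < config.multi_instance_rate:
                    if rng.random() < 0.5:
                        families = [primary, "affirmed_history"]
                    else:
                        # negated first, affirmed last: tie resolves positive
                        families = ["negated_history", primary]
                else:
                    families = [primary]
            elif j == neg_note:
                families = ["negated_history"]
            if j == fsh_note:
                families.append("family_history")
            elif j == fneg_note:
                families.append("family_negated")

            text, instances = generate_note(note_id, families, config, rng)
            note_date = (base + timedelta(days=day_offsets[j])).isoformat()
            notes.append(
                Note(note_id=note_id, patient_id=pid, date=note_date,
                     note_type="progress note", text=text)
            )
            psh_label, fsh_label = _note_labels(instances)
            gold.append(
                GoldRecord(note_id=note_id, patient_id=pid, date=note_date,
                           psh_label=psh_label, fsh_label=fsh_label,
                           instances=instances)
            )

        first_date = base + timedelta(days=day_offsets[0])
        patient_psh = any(g.psh_label == doclabels.POSITIVE for g in gold[-n_notes:])
        if patient_psh and rng.random() < config.icd_coding_rate:
            code = str(stb_codes[int(rng.integers(len(stb_codes)))])
            icd_date = first_date - timedelta(days=int(rng.integers(30, 400)))
            icd_rows.append({"patient_id": pid, "code": code, "date": icd_date.isoformat()})
        if rng.random() < 0.3:
            code = str(other_codes[int(rng.integers(len(other_codes)))])
            icd_date = first_date - timedelta(days=int(rng.integers(0, 200)))
            icd_rows.append({"patient_id": pid, "code": code, "date": icd_date.isoformat()})

    icd = pd.DataFrame(icd_rows, columns=["patient_id", "code", "date"])
    return CorpusBundle(notes=notes, gold=gold, icd=icd, config=config)


# ---------------------------------------------------------------------------
# Bundle views and serialization


def gold_note_labels(bundle: CorpusBundle, scope: str) -> dict[str, str]:
    """note_id -> gold label for one scope ("psh" or "fsh")."""
    attr = "psh_label" if scope == "psh" else "fsh_label"
    return {g.note_id: getattr(g, attr) for g in bundle.gold}


def gold_patient_labels(bundle: CorpusBundle, scope: str) -> dict[str, str]:
    attr = "psh_label" if scope == "psh" else "fsh_label"
    out: dict[str, str] = {}
    for g in bundle.gold:
        if getattr(g, attr) == doclabels.POSITIVE:
            out[g.patient_id] = doclabels.POSITIVE
        else:
            out.setdefault(g.patient_id, doclabels.NEGATIVE)
    return out


def planted_instance_records(bundle: CorpusBundle) -> list[dict]:
    return [asdict(p) for g in bundle.gold for p in g.instances]


def index_dates(bundle: CorpusBundle) -> dict[str, date]:
    """Earliest analyzed note date per patient."""
    out: dict[str, date] = {}
    for g in bundle.gold:
        d = date.fromisoformat(g.date)
        if g.patient_id not in out or d < out[g.patient_id]:
            out[g.patient_id] = d
    return out


def write_bundle(bundle: CorpusBundle, outdir: str | Path) -> None:
    """Write the bundle directory: notes/*.txt + ann/*.ann (BRAT),
    corpus.jsonl, gold.csv, instances.jsonl, icd.csv, config.yaml."""
    outdir = Path(outdir)
    (outdir / "notes").mkdir(parents=True, exist_ok=True)
    (outdir / "ann").mkdir(parents=True, exist_ok=True)
    write_corpus(bundle.notes, outdir / "corpus.jsonl")
    by_note = {g.note_id: g for g in bundle.gold}
    for note in bundle.notes:
        g = by_note[note.note_id]
        entities = [
            BratEntity(
                id=f"T{k+1}",
                type=f"{p.category}_{p.scope}_{p.polarity}",
                start=p.start,
                end=p.end,
                surface=p.surface,
            )
            for k, p in enumerate(sorted(g.instances, key=lambda p: p.start))
        ]
        write_brat(
            BratDocument(text=note.text, entities=entities),
            outdir / "notes" / f"{note.note_id}.txt",
            outdir / "ann" / f"{note.note_id}.ann",
        )
    pd.DataFrame(
        [
            {"note_id": g.note_id, "patient_id": g.patient_id, "date": g.date,
             "psh_label": g.psh_label, "fsh_label": g.fsh_label}
            for g in bundle.gold
        ]
    ).to_csv(outdir / "gold.csv", index=False)
    (outdir / "instances.jsonl").write_text(
        "".join(json.dumps(r, sort_keys=True) + "\n" for r in planted_instance_records(bundle))
    )
    bundle.icd.to_csv(outdir / "icd.csv", index=False)
    cfg = asdict(bundle.config)
    cfg["notes_per_patient"] = list(bundle.config.notes_per_patient)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
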