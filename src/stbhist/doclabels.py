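"""Note- and patient-level label aggregation.

A note's PSH (personal suicidal history) and FSH (family suicidal
history) labels are derived from its extracted instances by the
single-instance / majority-polling / last-mention rule used when the
gold standard is annotated:

* no instance of that scope -> NEGATIVE;
* one instance -> POSITIVE iff it is affirmed;
* several instances -> majority polarity; a tie is resolved by the
  polarity of the last-mentioned instance (greatest concept offset).

Patients are POSITIVE for a scope iff any of their notes is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .rules import AFFIRMED, FAMILY, PERSONAL, HistoryInstance

POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"
NO_MENTION = "NO_MENTION"


@dataclass
class DocumentClassification:
    note_id: str
    psh_label: str
    fsh_label: str
    psh_instances: list[HistoryInstance] = field(default_factory=list)
    fsh_instances: list[HistoryInstance] = field(default_factory=list)


@dataclass
class PatientClassification:
    patient_id: str
    psh_label: str
    fsh_label: str
    note_ids: list[str] = field(default_factory=list)


def classify_instances(instances: Sequence[HistoryInstance]) -> str:
    """Apply the single-instance / majority / last-mention rule to the
    instances of one scope."""
    scopes = {i.scope for i in instances}
    if len(scopes) > 1:
        raise ValueError(f"instances mix scopes {sorted(scopes)}; classify one scope at a time")
    if not instances:
        return NEGATIVE
    ordered = sorted(instances, key=HistoryInstance.sort_key)
    n_affirmed = sum(1 for i in ordered if i.polarity == AFFIRMED)
    n_negated = len(ordered) - n_affirmed
    if n_affirmed != n_negated:
        return POSITIVE if n_affirmed > n_negated else NEGATIVE
    return POSITIVE if ordered[-1].polarity == AFFIRMED else NEGATIVE


def three_way_label(instances: Sequence[HistoryInstance]) -> str:
    """POSITIVE / NEGATED / NO_MENTION variant for error analysis; the
    binary form is canonical."""
    if not instances:
        return NO_MENTION
    return POSITIVE if classify_instances(instances) == POSITIVE else "NEGATED"


def classify_note(note_id: str, instances: Sequence[HistoryInstance]) -> DocumentClassification:
    """Partition a note's instances by scope and label each scope."""
    psh = sorted((i for i in instances if i.scope == PERSONAL), key=HistoryInstance.sort_key)
    fsh = sorted((i for i in instances if i.scope == FAMILY), key=HistoryInstance.sort_key)
    return DocumentClassification(
        note_id=note_id,
        psh_label=classify_instances(psh),
        fsh_label=classify_instances(fsh),
        psh_instances=psh,
        fsh_instances=fsh,
    )


def aggregate_patients(
    classifications: Iterable[DocumentClassification],
    note_to_patient: Mapping[str, str],
) -> list[PatientClassification]:
    """Any-positive roll-up of note labels per patient, ordered by
    patient id."""
    by_patient: dict[str, list[DocumentClassification]] = {}
    for c in classifications:
        by_patient.setdefault(note_to_patient[c.note_id], []).append(c)
    out = []
    for pid in sorted(by_patient):
        docs = by_patient[pid]
        out.append(
            PatientClassification(
                patient_id=pid,
                psh_label=POSITIVE if any(d.psh_label == POSITIVE for d in docs) else NEGATIVE,
                fsh_label=POSITIVE if any(d.fsh_label == POSITIVE for d in docs) else NEGATIVE,
                note_ids=[d.note_id for d in docs],
            )
        )
    return out


def classifications_to_frame(
    classifications: Iterable[DocumentClassification],
    note_to_patient: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Note-level classification table (one row per note)."""
    rows = [
        {
            "note_id": c.note_id,
            "patient_id": note_to_patient.get(c.note_id, "") if note_to_patient else "",
            "psh_label": c.psh_label,
            "fsh_label": c.fsh_label,
            "n_psh_instances": len(c.psh_instances),
            "n_fsh_instances": len(c.fsh_instances),
        }
        for c in classifications
    ]
    return pd.DataFrame(rows, columns=[
        "note_id", "patient_id", "psh_label", "fsh_label",
        "n_psh_instances", "n_fsh_instances",
    ])
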