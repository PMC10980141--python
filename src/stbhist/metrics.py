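"""Evaluation: confusion counts, precision/recall/F1 with macro and
weighted (support-weighted) averaging, Cohen's kappa for annotator
agreement, the ICD-code baseline comparison, and per-template-family
recall for error analysis.

Zero-division convention: precision, recall and F1 are 0 when their
denominator is 0; the report carries a flag when this occurred so that
collapsed classes are visible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import confusion_matrix

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    labels: tuple
    per_class: dict  # label -> {"tp", "fp", "fn", "tn"}
    n: int


@dataclass
class EvalReport:
    accuracy: float
    per_class: dict  # label -> {"precision", "recall", "f1", "support"}
    macro: dict  # {"precision", "recall", "f1"}
    weighted: dict
    n: int
    zero_division_hit: bool = False

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "macro": self.macro,
            "weighted": self.weighted,
            "n": self.n,
            "zero_division_hit": self.zero_division_hit,
        }


def compute_confusion(gold: Sequence, pred: Sequence, labels: Sequence | None = None) -> ConfusionCounts:
    """Per-class tp/fp/fn/tn over a fixed label set."""
    if len(gold) != len(pred):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(pred)} predicted")
    gold_set, pred_set = set(gold), set(pred)
    if labels is None:
        if gold and pred and gold_set.isdisjoint(pred_set):
            raise ValueError(
                f"gold labels {sorted(map(str, gold_set))} and predicted labels "
                f"{sorted(map(str, pred_set))} are disjoint"
            )
        labels = sorted(gold_set | pred_set)
    else:
        labels = list(labels)
        stray = (gold_set | pred_set) - set(labels)
        if stray:
            raise ValueError(f"values outside the label set: {sorted(map(str, stray))}")
    cm = confusion_matrix(gold, pred, labels=labels)
    n = int(cm.sum())
    per_class = {}
    for i, lab in enumerate(labels):
        tp = int(cm[i, i])
        fp = int(cm[:, i].sum() - tp)
        fn = int(cm[i, :].sum() - tp)
        per_class[lab] = {"tp": tp, "fp": fp, "fn": fn, "tn": n - tp - fp - fn}
    return ConfusionCounts(labels=tuple(labels), per_class=per_class, n=n)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den else (0.0, True)


def compute_prf(counts: ConfusionCounts, averaging: str = "per_class") -> dict:
    """Precision/recall/F1 from confusion counts.

    averaging: "per_class" (dict per label), "macro" (unweighted mean),
    or "weighted" (support-weighted mean).
    """
    per_class = {}
    hit = False
    for lab in counts.labels:
        c = counts.per_class[lab]
        p, h1 = _safe_div(c["tp"], c["tp"] + c["fp"])
        r, h2 = _safe_div(c["tp"], c["tp"] + c["fn"])
        f1, h3 = _safe_div(2 * p * r, p + r)
        hit = hit or h1 or h2 or h3
        per_class[lab] = {"precision": p, "recall": r, "f1": f1, "support": c["tp"] + c["fn"]}
    if averaging == "per_class":
        return per_class
    metrics = ("precision", "recall", "f1")
    if averaging == "macro":
        return {m: float(np.mean([per_class[l][m] for l in counts.labels])) for m in metrics}
    if averaging == "weighted":
        supports = np.array([per_class[l]["support"] for l in counts.labels], dtype=float)
        total = supports.sum()
        if total == 0:
            return {m: 0.0 for m in metrics}
        return {
            m: float(np.sum([per_class[l][m] * per_class[l]["support"] for l in counts.labels]) / total)
            for m in metrics
        }
    raise ValueError(f"unknown averaging {averaging!r}")


def evaluate(gold: Sequence, pred: Sequence, labels: Sequence | None = None) -> EvalReport:
    """Full report: accuracy plus per-class/macro/weighted P, R, F1."""
    counts = compute_confusion(gold, pred, labels)
    per_class = compute_prf(counts, "per_class")
    correct = sum(counts.per_class[l]["tp"] for l in counts.labels)
    zero_hit = any(
        counts.per_class[l]["tp"] + counts.per_class[l]["fp"] == 0
        or per_class[l]["support"] == 0
        for l in counts.labels
    )
    return EvalReport(
        accuracy=correct / counts.n if counts.n else 0.0,
        per_class=per_class,
        macro=compute_prf(counts, "macro"),
        weighted=compute_prf(counts, "weighted"),
        n=counts.n,
        zero_division_hit=zero_hit,
    )


def cohens_kappa(annotations_a: Sequence, annotations_b: Sequence) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e) with
    p_e from the marginal products. Returns 1.0 when both observed and
    expected agreement are 1; NaN when p_e = 1 but p_o < 1."""
    if len(annotations_a) != len(annotations_b):
        raise ValueError("annotation sequences differ in length")
    n = len(annotations_a)
    if n == 0:
        raise ValueError("empty annotation sequences")
    labels = sorted(set(annotations_a) | set(annotations_b))
    p_o = sum(a == b for a, b in zip(annotations_a, annotations_b)) / n
    p_e = sum(
        (sum(a == lab for a in annotations_a) / n) * (sum(b == lab for b in annotations_b) / n)
        for lab in labels
    )
    if math.isclose(p_e, 1.0):
        return 1.0 if math.isclose(p_o, 1.0) else float("nan")
    return (p_o - p_e) / (1 - p_e)


# ---------------------------------------------------------------------------
# ICD-code baseline


@dataclass
class BaselineComparison:
    n_gold_positive: int
    n_coded_prior: int
    n_detected: int
    coded_fraction: float
    detected_fraction: float
    skipped_records: list = field(default_factory=list)


def load_code_set(source: str | Path | None = None) -> list[str]:
    """Load the STB ICD-9/10 code set (packaged default when None).

    Entries are plain codes ("R45.851") matched by prefix after dot
    removal, or category ranges ("X71-X83", "E950-E959")."""
    if source is None:
        text = resources.files("stbhist.data").joinpath("icd_codes.yaml").read_text()
    else:
        text = Path(source).read_text()
    data = yaml.safe_load(text)
    return [str(c) for key in ("icd10", "icd9") for c in data.get(key, [])]


def _norm(code: str) -> str:
    return str(code).replace(".", "").replace(" ", "").upper()


def code_matches(code: str, entry: str) -> bool:
    code = _norm(code)
    if "-" in entry:
        lo, hi = (_norm(p) for p in entry.split("-", 1))
        alpha = lo.rstrip("0123456789")
        if not code.startswith(alpha) or alpha != hi.rstrip("0123456789"):
            return False
        width = len(lo) - len(alpha)
        digits = code[len(alpha) : len(alpha) + width]
        if len(digits) < width or not digits.isdigit():
            return False
        return int(lo[len(alpha):]) <= int(digits) <= int(hi[len(alpha):])
    return code.startswith(_norm(entry))


def icd_baseline_compare(
    gold_positive_patients: Iterable[str],
    icd_records: pd.DataFrame,
    code_set: Sequence[str],
    index_dates: Mapping[str, date],
    detected_patients: Iterable[str],
) -> BaselineComparison:
    """Among gold-positive patients, count those with a qualifying ICD
    code dated on or before their index date (earliest analyzed note),
    and those detected by the classifier; report both fractions.

    ``icd_records`` columns: patient_id, code, date (ISO-8601).
    Unparseable dates are skipped and logged, not fatal.
    """
    gold = sorted(set(gold_positive_patients))
    detected = set(detected_patients)
    skipped: list[str] = []
    coded: set[str] = set()
    for rec in icd_records.itertuples(index=False):
        pid, code, raw_date = str(rec.patient_id), str(rec.code), str(rec.date)
        if pid not in index_dates or pid not in set(gold):
            continue
        try:
            rec_date = date.fromisoformat(raw_date)
        except ValueError:
            skipped.append(f"{pid}/{code}/{raw_date}")
            logger.warning("skipping ICD record with unparseable date: %s %s %s", pid, code, raw_date)
            continue
        if rec_date <= index_dates[pid] and any(code_matches(code, e) for e in code_set):
            coded.add(pid)
    n = len(gold)
    n_coded = len(coded)
    n_det = len(detected & set(gold))
    return BaselineComparison(
        n_gold_positive=n,
        n_coded_prior=n_coded,
        n_detected=n_det,
        coded_fraction=n_coded / n if n else 0.0,
        detected_fraction=n_det / n if n else 0.0,
        skipped_records=skipped,
    )


def instance_recall_by_family(
    planted: Iterable[Mapping],
    extracted: Mapping[str, Sequence],
) -> dict:
    """Instance-level recall per template family.

    ``planted``: gold instance records with note_id, start, end,
    polarity, scope and template ``family``. ``extracted``: note_id ->
    extracted HistoryInstance list. A planted instance counts as
    recovered when an extracted instance has the same concept offsets,
    polarity, and scope.
    """
    hits: dict[str, int] = {}
    totals: dict[str, int] = {}
    for g in planted:
        fam = g["family"]
        totals[fam] = totals.get(fam, 0) + 1
        for inst in extracted.get(g["note_id"], []):
            if (
                inst.concept.start == g["start"]
                and inst.concept.end == g["end"]
                and inst.polarity == g["polarity"]
                and inst.scope == g["scope"]
            ):
                hits[fam] = hits.get(fam, 0) + 1
                break
    return {fam: hits.get(fam, 0) / totals[fam] for fam in sorted(totals)}
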