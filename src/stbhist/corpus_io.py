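"""Readers and writers for on-disk formats: note corpora (JSONL/CSV),
BRAT standoff annotation pairs, and run logging.

Readers reject malformed records rather than coercing them; every
rejection names the offending record. Dates are ISO-8601 only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger("stbhist")

REQUIRED_NOTE_FIELDS = ("note_id", "patient_id", "date", "note_type", "text")

_ENTITY_RE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$", re.DOTALL)


class CorpusError(ValueError):
    """Malformed corpus record (missing field, duplicate id, bad date)."""


class BratError(ValueError):
    """Malformed BRAT standoff content."""


@dataclass
class Note:
    """One clinical document: the unit of classification."""

    note_id: str
    patient_id: str
    date: str  # ISO-8601
    note_type: str
    text: str


@dataclass
class BratEntity:
    id: str  # "T<k>"
    type: str
    start: int
    end: int
    surface: str


@dataclass
class BratDocument:
    text: str
    entities: list[BratEntity] = field(default_factory=list)


def _validate_note(rec: dict, where: str) -> Note:
    for f in REQUIRED_NOTE_FIELDS:
        if f not in rec or rec[f] is None:
            raise CorpusError(f"{where}: missing required field {f!r}")
    try:
        date.fromisoformat(str(rec["date"]))
    except ValueError as exc:
        raise CorpusError(f"{where}: date {rec['date']!r} is not ISO-8601") from exc
    return Note(
        note_id=str(rec["note_id"]),
        patient_id=str(rec["patient_id"]),
        date=str(rec["date"]),
        note_type=str(rec["note_type"]),
        text=str(rec["text"]),
    )


def read_corpus(path: str | Path, fmt: str | None = None) -> list[Note]:
    """Load a note corpus from JSONL or CSV (format inferred from the
    suffix when *fmt* is None). Duplicate note_ids are rejected."""
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    notes: list[Note] = []
    if fmt == "jsonl":
        for i, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{i}: invalid JSON: {exc}") from exc
            notes.append(_validate_note(rec, f"{path}:{i}"))
    elif fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for i, rec in enumerate(df.to_dict(orient="records"), start=2):
            notes.append(_validate_note(rec, f"{path}:row {i}"))
    else:
        raise CorpusError(f"unknown corpus format {fmt!r}")
    seen: set[str] = set()
    for n in notes:
        if n.note_id in seen:
            raise CorpusError(f"{path}: duplicate note_id {n.note_id!r}")
        seen.add(n.note_id)
    logger.info("read %d notes from %s", len(notes), path)
    return notes


def write_corpus(notes: Iterable[Note], path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    rows = [vars(n) for n in notes]
    if fmt == "jsonl":
        path.write_text("".join(json.dumps(r, sort_keys=True) + "\n" for r in rows))
    elif fmt == "csv":
        pd.DataFrame(rows, columns=list(REQUIRED_NOTE_FIELDS)).to_csv(path, index=False)
    else:
        raise CorpusError(f"unknown corpus format {fmt!r}")


def read_brat(txt_path: str | Path, ann_path: str | Path) -> BratDocument:
    """Parse a BRAT .txt/.ann pair. Only entity ("T") lines are
    supported; relation/attribute/note lines are skipped with a warning,
    discontinuous spans are rejected."""
    text = Path(txt_path).read_text()
    entities: list[BratEntity] = []
    seen_ids: set[str] = set()
    for i, line in enumerate(Path(ann_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith("T"):
            logger.warning("%s:%d: skipping non-entity line %r", ann_path, i, line[:40])
            continue
        fields = line.split("\t")
        if len(fields) > 1 and ";" in fields[1]:
            raise BratError(f"{ann_path}:{i}: discontinuous spans are unsupported")
        m = _ENTITY_RE.match(line)
        if m is None:
            raise BratError(f"{ann_path}:{i}: cannot parse entity line {line!r}")
        eid, etype, start, end, surface = m.group(1), m.group(2), int(m.group(3)), int(m.group(4)), m.group(5)
        if eid in seen_ids:
            raise BratError(f"{ann_path}:{i}: duplicate entity id {eid}")
        seen_ids.add(eid)
        if text[start:end] != surface:
            raise BratError(
                f"{ann_path}: entity {eid}: surface {surface!r} != text slice {text[start:end]!r}"
            )
        entities.append(BratEntity(id=eid, type=etype, start=start, end=end, surface=surface))
    return BratDocument(text=text, entities=entities)


def write_brat(doc: BratDocument, txt_path: str | Path, ann_path: str | Path) -> None:
    """Write a BRAT pair; write-then-read is the identity."""
    Path(txt_path).write_text(doc.text)
    lines = [
        f"{e.id}\t{e.type} {e.start} {e.end}\t{e.surface}" for e in doc.entities
    ]
    Path(ann_path).write_text("".join(line + "\n" for line in lines))


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def config_hash(obj) -> str:
    """Stable short hash of a (dataclass or dict) configuration, for the
    per-run log."""
    data = vars(obj) if hasattr(obj, "__dataclass_fields__") else dict(obj)
    blob = json.dumps(data, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
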