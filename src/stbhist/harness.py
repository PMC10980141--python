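"""Trainable-classifier harness: cross-validation protocol, the
fine-tuning configuration, and classifier backends.

The evaluation protocol is repeated random sub-sampling: each of the
``folds`` rounds draws a fresh random 80/20 train/test partition (a
conventional disjoint-fold mode is available). Per-fold scores are
summarised as mean +/- sample standard deviation, with the weighted
(support-weighted) average as the headline metric since PSH/FSH corpora
are unbalanced.

Two backends satisfy the same contract:

* ``ReferenceBackend`` — a regularised logistic classifier over token
  counts; deterministic, dependency-light, and fast enough for tests.
* ``TransformerBackend`` — the fine-tuned clinical encoder path (frozen
  early layers, tuned head); optional, requires torch + transformers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression

from .metrics import EvalReport, evaluate
from .spans import SpanRecord

SUMMARY_METRICS = (
    "accuracy",
    "weighted_precision",
    "weighted_recall",
    "weighted_f1",
    "macro_precision",
    "macro_recall",
    "macro_f1",
)


@dataclass
class TrainConfig:
    """Fine-tuning and CV configuration (defaults follow the published
    protocol: batch 16, learning rate 1e-5, dropout 0.3, 5 epochs,
    AdamW, early layers frozen, 10 random 80/20 splits)."""

    batch_size: int = 16
    learning_rate: float = 1e-5
    dropout: float = 0.3
    epochs: int = 5
    optimizer_name: str = "adamw"
    freeze_early_layers: bool = True
    window_n: int = 16
    seed: int = 0
    folds: int = 10
    test_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")
        if min(self.batch_size, self.epochs, self.folds) < 1:
            raise ValueError("batch_size, epochs and folds must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class CVSplit:
    fold: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


class ClassifierBackend(Protocol):
    """Contract every backend satisfies: deterministic given the seed,
    predictions defined for unseen records, labels drawn from the
    training label set."""

    def fit(self, texts: Sequence[str], labels: Sequence[str], config: TrainConfig) -> None: ...

    def predict(self, texts: Sequence[str]) -> list[str]: ...

    def predict_scores(self, texts: Sequence[str]) -> list[dict]: ...


def make_cv_splits(
    doc_ids: Sequence[str],
    folds: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
    mode: str = "subsample",
) -> list[CVSplit]:
    """``folds`` random splits of the document ids.

    mode="subsample" (default): independent random 80/20 partitions,
    one per fold. mode="disjoint": conventional k-fold whose test sets
    partition the ids (test_fraction ignored).
    """
    ids = list(doc_ids)
    n = len(ids)
    if n < 5:
        raise ValueError(f"need at least 5 documents for cross-validation, got {n}")
    rng = np.random.default_rng(seed)
    splits: list[CVSplit] = []
    if mode == "subsample":
        n_test = round(test_fraction * n)
        if not (0 < n_test < n):
            raise ValueError("test_fraction leaves an empty train or test set")
        for k in range(folds):
            perm = rng.permutation(n)
            test = sorted(ids[i] for i in perm[:n_test])
            train = sorted(ids[i] for i in perm[n_test:])
            splits.append(CVSplit(fold=k, train_ids=tuple(train), test_ids=tuple(test)))
    elif mode == "disjoint":
        perm = rng.permutation(n)
        chunks = np.array_split(perm, folds)
        for k, chunk in enumerate(chunks):
            test = sorted(ids[i] for i in chunk)
            train = sorted(ids[i] for i in perm if ids[i] not in set(test))
            splits.append(CVSplit(fold=k, train_ids=tuple(train), test_ids=tuple(test)))
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return splits


class ReferenceBackend:
    """Regularised logistic classifier over token-count features."""

    def __init__(self, seed: int = 0, C: float = 1.0):
        self.seed = seed
        self.C = C
        self._vec: CountVectorizer | None = None
        self._clf: LogisticRegression | None = None

    def fit(self, texts: Sequence[str], labels: Sequence[str], config: TrainConfig) -> None:
        self._vec = CountVectorizer(lowercase=True, token_pattern=r"\S+")
        X = self._vec.fit_transform(texts)
        self._clf = LogisticRegression(
            C=self.C, max_iter=2000, random_state=config.seed if config else self.seed
        )
        self._clf.fit(X, list(labels))

    def _check_fitted(self) -> None:
        if self._vec is None or self._clf is None:
            raise RuntimeError("backend has not been fitted")

    def predict(self, texts: Sequence[str]) -> list[str]:
        self._check_fitted()
        return list(self._clf.predict(self._vec.transform(texts)))

    def predict_scores(self, texts: Sequence[str]) -> list[dict]:
        self._check_fitted()
        proba = self._clf.predict_proba(self._vec.transform(texts))
        return [dict(zip(self._clf.classes_, row)) for row in proba]


class TransformerBackend:
    """Fine-tuned clinical encoder classifier (optional).

    Uses a pretrained encoder (e.g. a clinical BERT variant) with the
    early layers frozen and the last ``n_trainable_layers`` plus the
    classification head fine-tuned under the TrainConfig hyperparameters.
    Requires the ``torch`` and ``transformers`` packages; constructing it
    without them raises immediately with a clear message.
    """

    def __init__(self, model_name: str, n_trainable_layers: int = 2):
        try:
            import torch  # noqa: F401
            import transformers  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "TransformerBackend requires the optional 'torch' and 'transformers' "
                "packages; install them or use ReferenceBackend"
            ) from exc
        self.model_name = model_name
        self.n_trainable_layers = n_trainable_layers
        raise NotImplementedError(
            "transformer fine-tuning is intentionally out of desk scope; "
            "implement fit/predict against the ClassifierBackend contract"
        )


@dataclass
class FoldResult:
    fold: int
    n_train: int
    n_test: int
    report: EvalReport | None
    skipped: bool = False
    warning: str | None = None


@dataclass
class CVResult:
    folds: list[FoldResult]
    summary: dict  # metric -> {"mean", "sd"}

    def to_dict(self) -> dict:
        return {
            "folds": [
                {
                    "fold": f.fold,
                    "n_train": f.n_train,
                    "n_test": f.n_test,
                    "skipped": f.skipped,
                    "warning": f.warning,
                    "report": f.report.to_dict() if f.report else None,
                }
                for f in self.folds
            ],
            "summary": self.summary,
        }


def _flat_metrics(report: EvalReport) -> dict:
    out = {"accuracy": report.accuracy}
    for avg in ("weighted", "macro"):
        for m in ("precision", "recall", "f1"):
            out[f"{avg}_{m}"] = getattr(report, avg)[m]
    return out


def run_cv(
    dataset: Sequence[SpanRecord],
    backend_factory: Callable[[], ClassifierBackend],
    config: TrainConfig,
    mode: str = "subsample",
) -> CVResult:
    """Fit/score the backend over the CV splits and summarise each
    metric as mean +/- sample sd across scored folds. Folds whose
    training half contains a single class are skipped with a warning."""
    by_id = {r.doc_id: r for r in dataset}
    if len(by_id) != len(dataset):
        raise ValueError("duplicate doc_ids in span dataset")
    if len(set(r.label for r in dataset)) < 2:
        raise ValueError("dataset labels must contain at least two classes")
    splits = make_cv_splits(
        sorted(by_id), folds=config.folds, test_fraction=config.test_fraction,
        seed=config.seed, mode=mode,
    )
    folds: list[FoldResult] = []
    for split in splits:
        train = [by_id[i] for i in split.train_ids]
        test = [by_id[i] for i in split.test_ids]
        train_labels = {r.label for r in train}
        if len(train_labels) < 2:
            msg = f"fold {split.fold}: single-class training set {sorted(train_labels)}; skipped"
            warnings.warn(msg)
            folds.append(FoldResult(split.fold, len(train), len(test), None, True, msg))
            continue
        backend = backend_factory()
        backend.fit([r.text for r in train], [r.label for r in train], config)
        pred = backend.predict([r.text for r in test])
        report = evaluate([r.label for r in test], pred)
        folds.append(FoldResult(split.fold, len(train), len(test), report))
    scored = [f for f in folds if not f.skipped]
    summary = {}
    for metric in SUMMARY_METRICS:
        vals = np.array([_flat_metrics(f.report)[metric] for f in scored])
        summary[metric] = {
            "mean": float(vals.mean()) if len(vals) else float("nan"),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        }
    return CVResult(folds=folds, summary=summary)
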