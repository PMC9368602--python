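"""Multi-label evaluation metrics and cross-validation bookkeeping.

Five standard multi-label metrics over a labeled corpus: Hamming loss,
one-error, ranking loss, average precision, and micro-averaged
precision/recall/F1.  Conventions, fixed for determinism:

* scores missing from a record's map are 0 (a disease that never entered the
  patient's subnetwork has no evidence);
* score ties in one-error resolve to the lexicographically smallest label;
* ranking loss counts ties as loss (gold score <= non-gold score);
* ranks are a deterministic total order — strictly greater score first, then
  smaller label id among ties;
* a record whose gold set covers the whole label space is skipped by ranking
  loss and average precision (its complement is empty) with a warning;
* empty predictions give precision 0 by convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledPrediction",
    "MetricsReport",
    "hamming_loss",
    "one_error",
    "ranking_loss",
    "average_precision",
    "micro_f1",
    "evaluate",
    "kfold_split",
]


@dataclass
class LabeledPrediction:
    """One record's scores, predicted label set, and gold label set."""

    record_id: str
    scores: dict[str, float]
    predicted: set[str]
    gold: set[str]

    def score(self, label: str) -> float:
        return self.scores.get(label, 0.0)


@dataclass
class MetricsReport:
    hamming_loss: float
    one_error: float
    ranking_loss: float
    average_precision: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    n_records: int
    q_labels: int

    def to_dict(self) -> dict:
        return {
            "hamming_loss": self.hamming_loss,
            "one_error": self.one_error,
            "ranking_loss": self.ranking_loss,
            "average_precision": self.average_precision,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "micro_f1": self.micro_f1,
            "n_records": self.n_records,
            "q_labels": self.q_labels,
        }


def _label_space(
    preds: Sequence[LabeledPrediction], labels: Iterable[str] | None
) -> list[str]:
    if not preds:
        raise ValueError("need at least one prediction")
    if labels is not None:
        space = sorted(set(labels))
    else:
        space = sorted(
            set().union(*({*p.scores, *p.predicted, *p.gold} for p in preds))
        )
    if not space:
        raise ValueError("empty label space")
    for p in preds:
        stray = (p.predicted | p.gold) - set(space)
        if stray:
            raise ValueError(
                f"record {p.record_id!r} uses labels outside the label space: "
                f"{sorted(stray)[:5]}"
            )
    return space


def hamming_loss(
    preds: Sequence[LabeledPrediction], labels: Iterable[str] | None = None
) -> float:
    """Mean symmetric-difference size between predicted and gold sets, / Q."""
    space = _label_space(preds, labels)
    q = len(space)
    return sum(len(p.predicted ^ p.gold) / q for p in preds) / len(preds)


def _top_label(p: LabeledPrediction, space: Sequence[str]) -> str:
    return min(space, key=lambda lab: (-p.score(lab), lab))


def one_error(
    preds: Sequence[LabeledPrediction], labels: Iterable[str] | None = None
) -> float:
    """Fraction of records whose top-scoring label is not in the gold set."""
    space = _label_space(preds, labels)
    return sum(_top_label(p, space) not in p.gold for p in preds) / len(preds)


def ranking_loss(
    preds: Sequence[LabeledPrediction], labels: Iterable[str] | None = None
) -> float:
    """Mean fraction of (gold, non-gold) pairs ordered wrongly; ties count."""
    space = _label_space(preds, labels)
    total, n = 0.0, 0
    for p in preds:
        comp = [lab for lab in space if lab not in p.gold]
        if not p.gold or not comp:
            logger.warning(
                "record %s skipped by ranking_loss (gold covers label space)",
                p.record_id,
            )
            continue
        bad = sum(
            1
            for y in p.gold
            for yb in comp
            if p.score(y) <= p.score(yb)
        )
        total += bad / (len(p.gold) * len(comp))
        n += 1
    if n == 0:
        raise ValueError("no record with a non-empty gold complement")
    return total / n


def _ranks(p: LabeledPrediction, space: Sequence[str]) -> dict[str, int]:
    # total order: higher score first, smaller label id among ties
    order = sorted(space, key=lambda lab: (-p.score(lab), lab))
    return {lab: i + 1 for i, lab in enumerate(order)}


def average_precision(
    preds: Sequence[LabeledPrediction],
    labels: Iterable[str] | None = None,
    per_label_normalization: bool = True,
) -> float:
    """Mean precision at the ranks of the gold labels.

    With ``per_label_normalization`` (the default) each record's sum is
    divided by its gold-set size — the standard definition, and the only one
    whose perfect value is 1.  Setting it to ``False`` divides by the label
    space size Q instead (a variant sometimes printed in the literature).
    """
    space = _label_space(preds, labels)
    total, n = 0.0, 0
    for p in preds:
        if not p.gold:
            logger.warning("record %s skipped by average_precision (empty gold)", p.record_id)
            continue
        rank = _ranks(p, space)
        s = sum(
            sum(1 for y2 in p.gold if rank[y2] <= rank[y]) / rank[y] for y in p.gold
        )
        denom = len(p.gold) if per_label_normalization else len(space)
        total += s / denom
        n += 1
    if n == 0:
        raise ValueError("no record with a non-empty gold set")
    return total / n


def micro_f1(
    preds: Sequence[LabeledPrediction], labels: Iterable[str] | None = None
) -> tuple[float, float, float]:
    """Micro-averaged (precision, recall, F1) pooling TP/FP/FN over all labels."""
    _label_space(preds, labels)
    tp = sum(len(p.predicted & p.gold) for p in preds)
    fp = sum(len(p.predicted - p.gold) for p in preds)
    fn = sum(len(p.gold - p.predicted) for p in preds)
    if tp + fp == 0:
        logger.warning("no predicted labels at all; micro precision set to 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return precision, recall, f1


def evaluate(
    preds: Sequence[LabeledPrediction],
    labels: Iterable[str] | None = None,
    per_label_normalization: bool = True,
) -> MetricsReport:
    """All five metrics over one corpus, sharing a single label space."""
    space = _label_space(preds, labels)
    mp, mr, mf = micro_f1(preds, space)
    return MetricsReport(
        hamming_loss=hamming_loss(preds, space),
        one_error=one_error(preds, space),
        ranking_loss=ranking_loss(preds, space),
        average_precision=average_precision(preds, space, per_label_normalization),
        micro_precision=mp,
        micro_recall=mr,
        micro_f1=mf,
        n_records=len(preds),
        q_labels=len(space),
    )


def kfold_split(
    record_ids: Sequence[str], k: int, seed: int
) -> list[list[str]]:
    """Shuffle ids by *seed* and partition into k disjoint folds, sizes within 1."""
    n = len(record_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids = [record_ids[i] for i in perm]
    base, extra = divmod(n, k)
    folds, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(ids[start : start + size])
        start += size
    return folds


def mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1; 0.0 for a single value)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mean_sd of empty sequence")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
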