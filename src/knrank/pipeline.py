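"""End-to-end glue: record -> mentions -> subnetwork -> ranked prediction -> metrics.

A record is a JSONL-style dict carrying either raw ``text`` or pre-extracted
``mentions`` (list of ``{"surface", "negated"}``), plus optional
``gold_labels``.  The functions here wire the extraction, matching, ranking
and metrics modules together without adding behavior of their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .extraction import (
    FindingMention,
    Polarity,
    apply_negation,
    dictionary_tag,
    tags_to_mentions,
    tokenize,
)
from .kn import DEFAULT_SCHEME, KnowledgeNetwork, Lexicon, WeightScheme, lexicon_from_kn
from .matching import (
    MatchResult,
    PatientSubnetwork,
    affirmed_mentions,
    build_subnetwork,
    match_findings,
)
from .metrics import LabeledPrediction, MetricsReport, evaluate, kfold_split, mean_sd
from .ranking import RankResult, predict

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "extract_mentions", "predict_record", "evaluate_records",
           "evaluate_cv"]


@dataclass(frozen=True)
class PipelineConfig:
    """Hyperparameters of the prediction pipeline."""

    scheme: WeightScheme = DEFAULT_SCHEME
    damping: float = 0.85
    similarity_threshold: float = 0.5
    negation_window: int = 2
    tokenize_mode: str = "auto"


def extract_mentions(
    record: dict, lexicon: Lexicon, cfg: PipelineConfig = PipelineConfig()
) -> list[FindingMention]:
    """Polarity-annotated mentions for a record, from text or pre-extracted.

    Pre-extracted mentions bypass the tagger entirely; raw text goes through
    tokenization, dictionary tagging and negation scoping.
    """
    if "mentions" in record:
        out = []
        for i, m in enumerate(record["mentions"]):
            polarity = Polarity.NEGATED if m.get("negated", False) else Polarity.AFFIRMED
            out.append(
                FindingMention(
                    surface=m["surface"], span=(i, i + 1), polarity=polarity,
                    finding_id=m.get("finding_id"),
                )
            )
        return out
    seq = tokenize(record["text"], record_id=record.get("id"), mode=cfg.tokenize_mode)
    tags = dictionary_tag(seq, lexicon)
    mentions = tags_to_mentions(seq, tags)
    return apply_negation(seq, mentions, lexicon.negation_cues, cfg.negation_window)


def predict_record(
    record: dict,
    kn: KnowledgeNetwork,
    lexicon: Lexicon | None = None,
    cfg: PipelineConfig = PipelineConfig(),
    return_subnetwork: bool = False,
) -> RankResult | tuple[RankResult, PatientSubnetwork, list[MatchResult]]:
    """Full per-record pipeline; negated mentions never reach the subnetwork."""
    lex = lexicon if lexicon is not None else lexicon_from_kn(kn)
    mentions = extract_mentions(record, lex, cfg)
    matches = match_findings(
        affirmed_mentions(mentions), kn, threshold=cfg.similarity_threshold, lexicon=lex
    )
    sub = build_subnetwork(record["id"], matches, kn, scheme=cfg.scheme)
    result = predict(sub, d=cfg.damping)
    if return_subnetwork:
        return result, sub, matches
    return result


def _labeled(record: dict, result: RankResult) -> LabeledPrediction:
    return LabeledPrediction(
        record_id=record["id"],
        scores=result.nr,
        predicted=set(result.predicted),
        gold=set(record["gold_labels"]),
    )


def evaluate_records(
    records: Sequence[dict],
    kn: KnowledgeNetwork,
    lexicon: Lexicon | None = None,
    cfg: PipelineConfig = PipelineConfig(),
    labels: Iterable[str] | None = None,
) -> tuple[MetricsReport, list[LabeledPrediction]]:
    """Predict every record and score against its gold labels.

    The label space defaults to the union of gold and predicted labels over
    the corpus; diseases that never entered a record's subnetwork score 0.
    """
    missing = [r["id"] for r in records if not r.get("gold_labels")]
    if missing:
        raise ValueError(f"records lacking gold labels: {missing[:5]}")
    preds = [_labeled(r, predict_record(r, kn, lexicon, cfg)) for r in records]
    return evaluate(preds, labels=labels), preds


def evaluate_cv(
    records: Sequence[dict],
    kn: KnowledgeNetwork,
    k: int,
    seed: int,
    lexicon: Lexicon | None = None,
    cfg: PipelineConfig = PipelineConfig(),
    labels: Iterable[str] | None = None,
) -> dict:
    """k-fold evaluation: each fold scored as a held-out test set.

    The knowledge network is fixed evidence rather than a model fitted to the
    training folds, so the split only partitions records for evaluation; the
    report gives per-fold metrics and mean ± SD per metric.
    """
    ids = [r["id"] for r in records]
    by_id = {r["id"]: r for r in records}
    folds = kfold_split(ids, k=k, seed=seed)
    per_fold = []
    for fold in folds:
        report, _ = evaluate_records([by_id[i] for i in fold], kn, lexicon, cfg, labels)
        per_fold.append(report.to_dict())
    metric_keys = [
        "hamming_loss", "one_error", "ranking_loss", "average_precision",
        "micro_precision", "micro_recall", "micro_f1",
    ]
    summary = {}
    for key in metric_keys:
        mean, sd = mean_sd([f[key] for f in per_fold])
        summary[key] = {"mean": mean, "sd": sd}
    return {"k": k, "seed": seed, "folds": per_fold, "summary": summary}
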