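"""Match extracted mentions to KN findings and build the patient subnetwork.

Matching is exact-first (against finding display names and lexicon surfaces),
falling back to a string-similarity search over all KN findings — highest
similarity first, with deterministic tie-breaking.  The default similarity is
the character-bigram Dice coefficient; a semantic dictionary can be plugged in
as a replacement callable.

The patient subnetwork is a directed, weighted, bipartite DAG: every matched
finding points at every KN disease it supports, with the KN edge weight.  A
reserved calibration pair is injected — a gold-standard evidence node wired to
a standard-disease node with the auxiliary-level weight — whose rank later
serves as the prediction threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx

from .extraction import FindingMention, Polarity
from .kn import DEFAULT_SCHEME, KnowledgeNetwork, KNValidationError, Lexicon, WeightScheme

logger = logging.getLogger(__name__)

__all__ = [
    "STANDARD_DISEASE",
    "GOLD_STANDARD",
    "MatchMethod",
    "MatchResult",
    "PatientSubnetwork",
    "string_similarity",
    "match_findings",
    "build_subnetwork",
]

#: Reserved node ids, namespaced to avoid colliding with real KN identifiers.
STANDARD_DISEASE = "__STANDARD_DISEASE__"
GOLD_STANDARD = "__GOLD_STANDARD__"


class MatchMethod(str, Enum):
    EXACT = "exact"
    SIMILARITY = "similarity"
    UNMATCHED = "unmatched"


@dataclass
class MatchResult:
    mention: FindingMention
    matched_finding_id: str | None
    method: MatchMethod
    similarity: float

    def __post_init__(self) -> None:
        if self.method is MatchMethod.EXACT and self.similarity != 1.0:
            raise ValueError("exact matches must have similarity 1")
        if self.method is MatchMethod.UNMATCHED and self.matched_finding_id is not None:
            raise ValueError("unmatched results cannot carry a finding id")


def _bigrams(s: str) -> set[str]:
    return {s[i : i + 2] for i in range(len(s) - 1)}


def string_similarity(a: str, b: str) -> float:
    """Character-bigram Dice coefficient in [0, 1].

    For strings shorter than two characters the comparison falls back to
    single-character Dice.  Symmetric; identical strings score exactly 1.
    """
    if not a or not b:
        raise ValueError("string_similarity requires non-empty strings")
    if a == b:
        return 1.0
    if min(len(a), len(b)) < 2:
        sa, sb = set(a), set(b)
    else:
        sa, sb = _bigrams(a), _bigrams(b)
    denom = len(sa) + len(sb)
    if denom == 0:
        return 0.0
    return 2.0 * len(sa & sb) / denom


SimilarityFn = Callable[[str, str], float]


def match_findings(
    mentions: Sequence[FindingMention],
    kn: KnowledgeNetwork,
    threshold: float = 0.5,
    lexicon: Lexicon | None = None,
    similarity: SimilarityFn = string_similarity,
) -> list[MatchResult]:
    """Resolve each mention to a KN finding.

    Exact surface matches (mention ``finding_id``, finding display name, or
    lexicon surface) win outright.  Otherwise the finding with the highest
    similarity at or above *threshold* is chosen; ties break toward the
    shorter display name, then the lexicographically smaller id.  Mentions
    below threshold come back unmatched.

    Callers should pass affirmed mentions only — negated findings are
    evidence *against* and must not enter the subnetwork.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    exact: dict[str, str] = {}
    for fid in sorted(kn.findings):            # smaller id wins name collisions
        exact.setdefault(kn.findings[fid], fid)
    if lexicon is not None:
        for surface, fid in lexicon.entries:
            if fid in kn.findings:
                exact.setdefault(surface, fid)

    results: list[MatchResult] = []
    for m in mentions:
        if m.finding_id is not None and m.finding_id in kn.findings:
            results.append(MatchResult(m, m.finding_id, MatchMethod.EXACT, 1.0))
            continue
        fid = exact.get(m.surface)
        if fid is not None:
            results.append(MatchResult(m, fid, MatchMethod.EXACT, 1.0))
            continue
        best: tuple[float, int, str] | None = None   # (-sim, name length, id)
        best_sim = 0.0
        for cand, name in kn.findings.items():
            sim = similarity(m.surface, name)
            key = (-sim, len(name), cand)
            if best is None or key < best:
                best, best_sim = key, sim
        if best is not None and best_sim >= threshold and best_sim > 0.0:
            results.append(MatchResult(m, best[2], MatchMethod.SIMILARITY, best_sim))
        else:
            results.append(MatchResult(m, None, MatchMethod.UNMATCHED, best_sim))
    return results


@dataclass
class PatientSubnetwork:
    """Per-record directed weighted evidence graph, including the calibration pair."""

    record_id: str
    graph: nx.DiGraph
    scheme: WeightScheme = DEFAULT_SCHEME

    @property
    def finding_nodes(self) -> list[str]:
        return sorted(
            n for n, data in self.graph.nodes(data=True) if data.get("kind") == "finding"
        )

    @property
    def disease_nodes(self) -> list[str]:
        """Real (non-reserved) candidate disease nodes."""
        return sorted(
            n for n, data in self.graph.nodes(data=True) if data.get("kind") == "disease"
        )

    def to_dict(self) -> dict:
        """Debug dump: node lists and (src, dst, weight) edge triples."""
        return {
            "record_id": self.record_id,
            "findings": self.finding_nodes,
            "diseases": self.disease_nodes,
            "edges": sorted(
                (u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)
            ),
        }

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), ensure_ascii=False, indent=2), encoding="utf-8"
        )


def build_subnetwork(
    record_id: str,
    matches: Sequence[MatchResult],
    kn: KnowledgeNetwork,
    scheme: WeightScheme = DEFAULT_SCHEME,
) -> PatientSubnetwork:
    """Assemble the patient's binary-weighted subnetwork.

    Nodes: every matched finding (duplicates collapse), every KN disease
    adjacent to at least one of them, and the reserved calibration pair.
    Edges: all finding-to-disease KN edges among those nodes, with their KN
    weights, plus one gold-standard edge weighted like an auxiliary result.
    """
    if STANDARD_DISEASE in kn.diseases or STANDARD_DISEASE in kn.findings:
        raise KNValidationError(f"KN uses reserved id {STANDARD_DISEASE!r}")
    if GOLD_STANDARD in kn.diseases or GOLD_STANDARD in kn.findings:
        raise KNValidationError(f"KN uses reserved id {GOLD_STANDARD!r}")

    g = nx.DiGraph()
    matched = sorted(
        {r.matched_finding_id for r in matches if r.matched_finding_id is not None}
    )
    for fid in matched:
        g.add_node(fid, kind="finding")
    for fid in matched:
        for (f, d), e in kn.edges.items():
            if f == fid:
                if d not in g:
                    g.add_node(d, kind="disease")
                g.add_edge(fid, d, weight=e.weight)
    g.add_node(GOLD_STANDARD, kind="reserved")
    g.add_node(STANDARD_DISEASE, kind="reserved")
    g.add_edge(GOLD_STANDARD, STANDARD_DISEASE, weight=scheme.auxiliary)
    return PatientSubnetwork(record_id=record_id, graph=g, scheme=scheme)


def affirmed_mentions(mentions: Sequence[FindingMention]) -> list[FindingMention]:
    """Filter helper: drop negated mentions before matching."""
    return [m for m in mentions if m.polarity is Polarity.AFFIRMED]
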