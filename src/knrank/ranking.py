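"""Edge-weighted NodeRank and threshold-based multi-label prediction.

NodeRank is PageRank's damped recursion generalized to weighted edges:

    NR(v) = (1 - d) + d * sum over in-neighbors u of
            NR(u) * w(u, v) / outweight(u)

with damping d (default 0.85), all ranks initialized to 1, and the additive
term deliberately *not* divided by the node count.  Source nodes (no in-edges)
converge to exactly 1 - d; dangling nodes contribute nothing onward.

On a patient subnetwork the recursion closes after two sweeps, because the
graph is a findings-to-diseases DAG.  The standard-disease calibration node
always lands at (1 - d) + d(1 - d) = (1 - d)(1 + d): its single in-edge comes
from the gold-standard source.  A disease is predicted when its rank reaches
that threshold, which is algebraically the same as its *support ratio*

    sum over supporting findings f of  w(f, D) / outweight(f)

reaching 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .matching import GOLD_STANDARD, STANDARD_DISEASE, PatientSubnetwork

__all__ = [
    "NodeRankConvergenceError",
    "RankResult",
    "noderank_scores",
    "predict",
    "support_ratio",
]


class NodeRankConvergenceError(RuntimeError):
    """Raised when the iteration fails to reach tolerance within max_iter."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"NodeRank did not converge after {max_iter} iterations "
            f"(residual {residual:.3e})"
        )


def noderank_scores(
    graph: nx.DiGraph,
    d: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> dict[str, float]:
    """Fixed point of the weighted NodeRank recursion on *graph*.

    Edges must carry a positive ``weight`` attribute.  Jacobi iteration from
    all-ones; converges geometrically at rate d because each node's outgoing
    contribution fractions sum to at most 1.
    """
    if not 0.0 < d < 1.0:
        raise ValueError(f"damping d must be in (0, 1), got {d}")
    nodes = list(graph.nodes)
    if not nodes:
        return {}
    for u, v, data in graph.edges(data=True):
        if not data.get("weight", 0) > 0:
            raise ValueError(f"edge {u!r}->{v!r} must have positive weight")
    outweight = {
        u: sum(data["weight"] for _, _, data in graph.out_edges(u, data=True))
        for u in nodes
    }
    # in-edge contribution fractions, precomputed once
    frac = {
        v: [
            (u, data["weight"] / outweight[u])
            for u, _, data in graph.in_edges(v, data=True)
        ]
        for v in nodes
    }
    nr = {v: 1.0 for v in nodes}
    for _ in range(max_iter):
        new = {
            v: (1.0 - d) + d * sum(nr[u] * f for u, f in frac[v]) for v in nodes
        }
        residual = max(abs(new[v] - nr[v]) for v in nodes)
        nr = new
        if residual < tol:
            return nr
    raise NodeRankConvergenceError(residual, max_iter)


@dataclass
class RankResult:
    """Per-record NodeRank outcome.

    ``nr`` maps every candidate (non-reserved) disease to its rank;
    ``threshold`` is the standard-disease rank; ``predicted`` lists diseases
    with rank >= threshold, sorted by descending rank then ascending id.
    """

    record_id: str
    nr: dict[str, float]
    threshold: float
    predicted: list[str]

    def to_dict(self) -> dict:
        return {
            "id": self.record_id,
            "threshold": self.threshold,
            "scores": self.nr,
            "predicted": self.predicted,
        }


def predict(
    sub: PatientSubnetwork,
    d: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> RankResult:
    """Rank the subnetwork's candidate diseases and apply the threshold rule.

    The standard disease is a calibration device, not a diagnosis: reserved
    nodes are excluded from the output.  Inclusion uses >=, so a disease
    whose evidence exactly matches the gold-standard level is predicted.
    """
    scores = noderank_scores(sub.graph, d=d, tol=tol, max_iter=max_iter)
    threshold = scores[STANDARD_DISEASE]
    nr = {disease: scores[disease] for disease in sub.disease_nodes}
    predicted = sorted(
        (disease for disease, s in nr.items() if s >= threshold),
        key=lambda disease: (-nr[disease], disease),
    )
    return RankResult(record_id=sub.record_id, nr=nr, threshold=threshold, predicted=predicted)


def support_ratio(sub: PatientSubnetwork, disease_id: str) -> float:
    """Sum of w(f, D) / outweight(f) over the findings supporting *disease_id*.

    On the bipartite DAG every supporting finding has rank exactly (1 - d),
    so NR(D) = (1 - d) + d (1 - d) * support_ratio(D) and the threshold rule
    reduces to support_ratio >= 1 — a damping-free interpretability handle.
    """
    g = sub.graph
    if disease_id not in g:
        raise ValueError(f"disease {disease_id!r} not present in subnetwork")
    total = 0.0
    for u, _, data in g.in_edges(disease_id, data=True):
        outw = sum(dd["weight"] for _, _, dd in g.out_edges(u, data=True))
        total += data["weight"] / outw
    return total
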