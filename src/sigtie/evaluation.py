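"""Backbone-comparison and community-structure metrics.

Backbones produced by different filters (or at different significance
levels) are compared as edge sets (Jaccard index) and as weighted vectors
(cosine similarity over the union of their supports, absent edges counting
zero).  When a node partition is available, a backbone's community content
is summarized by the fraction of intra-group edges, by the ROC/AUC of the
implied intra-group-edge prediction task (ranking pairs by P-value), and by
the weighted modularity Q of the partition on the aggregate network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.metrics import roc_auc_score

from .significance import TieTest
from .temporal import AggregateCounts, Partition

__all__ = [
    "BackboneComparison",
    "jaccard",
    "cosine_similarity",
    "compare_backbones",
    "intra_fraction",
    "roc_auc_intra",
    "weighted_modularity",
]


def jaccard(pairs_a: Iterable, pairs_b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B| over edge sets; two empty backbones count as identical."""
    a, b = set(pairs_a), set(pairs_b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def cosine_similarity(weights_a: Mapping, weights_b: Mapping) -> float:
    """Cosine similarity of two weighted backbones.

    The inner product runs over the union of the two supports, with weight 0
    for a pair absent from one backbone; this is what lets the similarity
    fall below 1 when the supports differ even if shared weights agree.
    """
    support = set(weights_a) | set(weights_b)
    if not support:
        return 1.0
    wa = np.array([weights_a.get(p, 0.0) for p in support], dtype=float)
    wb = np.array([weights_b.get(p, 0.0) for p in support], dtype=float)
    if np.any(wa < 0) or np.any(wb < 0):
        raise ValueError("backbone weights must be non-negative")
    na, nb = np.linalg.norm(wa), np.linalg.norm(wb)
    if na == 0 or nb == 0:
        return 0.0
    return float(wa @ wb / (na * nb))


@dataclass(frozen=True)
class BackboneComparison:
    """Pairwise similarity of two backbones: set overlap and weighted overlap."""

    jaccard: float
    cosine: float
    size_a: int
    size_b: int
    size_intersection: int


def compare_backbones(weights_a: Mapping, weights_b: Mapping) -> BackboneComparison:
    a, b = set(weights_a), set(weights_b)
    return BackboneComparison(
        jaccard=jaccard(a, b),
        cosine=cosine_similarity(weights_a, weights_b),
        size_a=len(a),
        size_b=len(b),
        size_intersection=len(a & b),
    )


def intra_fraction(pairs: Iterable, partition: Partition):
    """Fraction of edges whose endpoints share a group label; None if empty."""
    pairs = list(pairs)
    if not pairs:
        return None
    return sum(partition.same_group(i, j) for (i, j) in pairs) / len(pairs)


def roc_auc_intra(tie_tests: Sequence[TieTest], partition: Partition):
    """AUC of intra-community edge prediction from the tie P-values.

    Positives are intra-group aggregate edges, negatives inter-group ones;
    the score is -p_value so that more significant ties rank higher.  The
    trapezoidal tie convention of the underlying ROC makes identical scores
    contribute 0.5.  Returns None when either class is empty.
    """
    if not tie_tests:
        return None
    y = np.array([partition.same_group(*t.pair) for t in tie_tests], dtype=int)
    if y.min() == y.max():
        return None
    scores = -np.array([t.p_value for t in tie_tests], dtype=float)
    return float(roc_auc_score(y, scores))


def weighted_modularity(counts: AggregateCounts, partition: Partition) -> float:
    """Newman weighted modularity Q of the partition on the aggregate network.

    Q = (1/2W) sum_ij [w_ij - s_i s_j / 2W] delta(c_i, c_j), with W the total
    edge weight.  Nodes without edges contribute nothing.
    """
    if counts.total_weight <= 0:
        raise ValueError("total weight must be positive")
    G = nx.Graph()
    G.add_nodes_from(counts.node_universe)
    for (i, j), m in counts.counts.items():
        if m > 0:
            G.add_edge(i, j, weight=m)
    by_group: dict = {}
    for node in counts.node_universe:
        by_group.setdefault(partition.label(node), set()).add(node)
    return float(nx.community.modularity(G, by_group.values(), weight="weight"))
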