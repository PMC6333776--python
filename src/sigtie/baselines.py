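"""Static-filter baselines: disparity filter, its snapshot-repeated variant.

The disparity (DP) filter tests each edge of a weighted static network
against a node-local null in which a node's strength s_i splits uniformly at
random among its k_i edges.  The closed-form P-value for an edge of weight w
seen from an endpoint of strength s and degree k is

    p = (1 - w/s)^(k - 1),        p = 1 when k = 1.

An edge enters the DP backbone if it is unlikely from at least one endpoint
(min of the two endpoint P-values below alpha); the stricter both-endpoint
convention is available via ``rule="both"``.

DP-R applies the DP filter to every snapshot of a temporal network
separately (weights = interactions within the window) and keeps a pair if it
is significant in at least one snapshot.  Its only notion of a significant
simultaneous triad is the trivial one: some snapshot contains all three
edges and all three are significant there.

A plain weight-threshold backbone is included as the crudest baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from sklearn.base import BaseEstimator

from .temporal import AggregateCounts, canonical_triple

__all__ = [
    "DPEdgeScore",
    "DisparityBackbone",
    "dp_pvalue",
    "dp_backbone",
    "dpr_backbone",
    "dpr_significant_triads",
    "threshold_backbone",
    "DisparityFilter",
]


def dp_pvalue(weight: float, strength: float, degree: int) -> float:
    """Disparity-filter P-value of an edge seen from one endpoint.

    ``(1 - w/s)^(k-1)``; a degree-one node offers no comparison and returns 1
    (its single edge can never be significant from that side).
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if weight <= 0:
        raise ValueError("weight must be positive")
    if weight > strength:
        raise ValueError(f"weight {weight} exceeds endpoint strength {strength}")
    if degree == 1:
        return 1.0
    return float((1.0 - weight / strength) ** (degree - 1))


@dataclass(frozen=True)
class DPEdgeScore:
    """Endpoint-wise disparity P-values for one edge; p_value is their min."""

    pair: tuple
    weight: float
    p_value_i: float
    p_value_j: float

    @property
    def p_value(self) -> float:
        return min(self.p_value_i, self.p_value_j)

    @property
    def p_value_both(self) -> float:
        return max(self.p_value_i, self.p_value_j)


@dataclass(frozen=True)
class DisparityBackbone:
    """DP scores for every edge, thresholded at ``alpha``."""

    alpha: float
    rule: str
    scores: tuple

    @property
    def pairs(self) -> set:
        return {s.pair for s in self.scores if self._keep(s)}

    @property
    def weights(self) -> dict:
        return {s.pair: s.weight for s in self.scores if self._keep(s)}

    def _keep(self, score: DPEdgeScore) -> bool:
        p = score.p_value if self.rule == "either" else score.p_value_both
        return p < self.alpha

    def p_values(self) -> dict:
        """pair -> min endpoint P-value for every scored edge (comparison API)."""
        return {s.pair: s.p_value for s in self.scores}


def _dp_scores(counts: AggregateCounts) -> list[DPEdgeScore]:
    strengths = counts.strengths
    degrees = counts.degrees
    scores = []
    for (i, j) in sorted(counts.pairs, key=repr):
        w = counts.counts[(i, j)]
        scores.append(
            DPEdgeScore(
                pair=(i, j),
                weight=w,
                p_value_i=dp_pvalue(w, strengths[i], degrees[i]),
                p_value_j=dp_pvalue(w, strengths[j], degrees[j]),
            )
        )
    return scores


def dp_backbone(counts: AggregateCounts, alpha: float, rule: str = "either") -> DisparityBackbone:
    """Disparity-filter backbone of a weighted aggregate network."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha={alpha} outside (0, 1]")
    if rule not in ("either", "both"):
        raise ValueError(f"rule must be 'either' or 'both', got {rule!r}")
    return DisparityBackbone(alpha=alpha, rule=rule, scores=tuple(_dp_scores(counts)))


def dpr_backbone(
    weighted_snapshots: Sequence[AggregateCounts],
    alpha: float,
    rule: str = "either",
) -> set:
    """DP-repeated backbone: pairs DP-significant in at least one snapshot."""
    kept: set = set()
    for snap in weighted_snapshots:
        kept |= dp_backbone(snap, alpha, rule=rule).pairs
    return kept


def dpr_significant_triads(
    weighted_snapshots: Sequence[AggregateCounts],
    alpha: float,
    rule: str = "either",
) -> set:
    """Triples whose three edges coexist, all significant, in some single snapshot."""
    triads: set = set()
    for snap in weighted_snapshots:
        sig = dp_backbone(snap, alpha, rule=rule).pairs
        neighbours: dict = {}
        for (i, j) in sig:
            neighbours.setdefault(i, set()).add(j)
            neighbours.setdefault(j, set()).add(i)
        for (i, j) in sig:
            for k in neighbours[i] & neighbours[j]:
                triads.add(canonical_triple(i, j, k))
    return triads


def threshold_backbone(counts: AggregateCounts, min_weight: float) -> set:
    """Global thresholding: keep pairs with m_obs >= min_weight."""
    return {p for p, m in counts.counts.items() if m >= min_weight}


class DisparityFilter(BaseEstimator):
    """Disparity filter as an estimator over an aggregate weighted network.

    Parameters
    ----------
    alpha : float
        Default significance level for :meth:`backbone`.
    rule : str
        ``"either"`` keeps an edge significant from at least one endpoint
        (min P-value), ``"both"`` requires both endpoints.

    Attributes
    ----------
    scores_ : tuple of DPEdgeScore, one per aggregate edge.
    """

    def __init__(self, alpha: float = 0.05, rule: str = "either"):
        self.alpha = alpha
        self.rule = rule

    def fit(self, X: AggregateCounts, y=None):
        if self.rule not in ("either", "both"):
            raise ValueError(f"rule must be 'either' or 'both', got {self.rule!r}")
        self.scores_ = tuple(_dp_scores(X))
        return self

    def backbone(self, alpha: float | None = None) -> DisparityBackbone:
        return DisparityBackbone(
            alpha=self.alpha if alpha is None else alpha,
            rule=self.rule,
            scores=self.scores_,
        )

    def p_values(self) -> dict:
        return {s.pair: s.p_value for s in self.scores_}
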