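"""Synthetic temporal networks: fitness-model null and the strong-tie benchmark.

The null generator draws one activity a'_i per node from a Beta distribution
and connects each pair (i, j) independently in every interval with
probability a'_i a'_j — i.e. data exactly from the temporal fitness model.

The strong-tie benchmark superimposes planted signal: a fixed fraction
(default 20%) of the pairs that interact at least once in the null layer is
selected uniformly at random and given an extra independent per-interval
interaction with probability ``boost``, OR-ed with the null events.  The
selected pairs are the ground-truth "strong" set against which backbone
detection is scored.  Because some strong pairs join two highly active
nodes, their boosted counts can remain compatible with the null — no filter
is expected to recover the strong set completely.

Defaults mirror the validation setting of the method: N = 300 nodes,
span T = 300 at resolution delta = 10 (tau = 30 snapshots), strong fraction
0.2.  The activity distribution Beta(2, 5) and boost 0.3 are this package's
documented choices (see docs/methods.md).

All randomness flows from one master seed through named substreams
(activities / null events / strong selection / boosts), so layers can be
varied independently while staying reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .temporal import SnapshotSequence

__all__ = [
    "SyntheticSpec",
    "SyntheticResult",
    "generate_null",
    "generate_benchmark",
    "detection_rates",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic generator.

    ``t_span / delta`` gives tau, the number of independent snapshots.
    ``beta_shape`` are the (alpha, beta) parameters of the activity
    distribution; ``boost`` the extra per-interval interaction probability
    of strong pairs.
    """

    n_nodes: int = 300
    t_span: float = 300.0
    delta: float = 10.0
    beta_shape: tuple = (2.0, 5.0)
    strong_fraction: float = 0.2
    boost: float = 0.3
    seed: int | None = None

    def __post_init__(self):
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if self.t_span <= 0 or self.delta <= 0:
            raise ValueError("t_span and delta must be positive")
        if not (0.0 <= self.strong_fraction <= 1.0):
            raise ValueError("strong_fraction must be in [0, 1]")
        if not (0.0 <= self.boost <= 1.0):
            raise ValueError("boost must be in [0, 1]")
        a, b = self.beta_shape
        if a <= 0 or b <= 0:
            raise ValueError("beta_shape parameters must be positive")

    @property
    def tau(self) -> int:
        return int(self.t_span // self.delta)


@dataclass(frozen=True)
class SyntheticResult:
    """Generated snapshots plus ground truth for validation."""

    snapshots: SnapshotSequence
    strong_set: frozenset
    activities_true: dict
    spec: SyntheticSpec


def _substreams(seed):
    """Independent generators for activities, null events, selection, boosts."""
    children = np.random.SeedSequence(seed).spawn(4)
    return tuple(np.random.default_rng(c) for c in children)


def _pair_index(n: int):
    iu = np.triu_indices(n, k=1)
    return iu


def _to_sequence(present: np.ndarray, pairs: list, spec: SyntheticSpec) -> SnapshotSequence:
    snapshots = tuple(
        frozenset(pairs[q] for q in np.flatnonzero(present[t])) for t in range(present.shape[0])
    )
    return SnapshotSequence(
        snapshots=snapshots,
        node_universe=tuple(range(spec.n_nodes)),
        delta=float(spec.delta),
    )


def _null_presence(spec: SyntheticSpec, rng_act, rng_null, activities=None):
    n = spec.n_nodes
    if activities is not None:
        a = np.asarray(activities, dtype=float)
        if a.shape != (n,) or np.any(a <= 0) or np.any(a > 1):
            raise ValueError("explicit activities must be n_nodes values in (0, 1]")
    else:
        a = rng_act.beta(*spec.beta_shape, size=n)
        a = np.clip(a, 1e-9, 1.0)  # activities live in (0, 1]
    iu = _pair_index(n)
    u = (a[:, None] * a[None, :])[iu]
    present = rng_null.random((spec.tau, u.size)) < u[None, :]
    pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
    return a, pairs, present


def generate_null(spec: SyntheticSpec, activities=None) -> SyntheticResult:
    """tau independent fitness-model snapshots; empty strong set.

    ``activities`` optionally fixes the per-node activities instead of
    drawing them from the Beta distribution (useful for calibration studies
    where the truth must be held fixed across replicates).
    """
    rng_act, rng_null, _, _ = _substreams(spec.seed)
    a, pairs, present = _null_presence(spec, rng_act, rng_null, activities)
    return SyntheticResult(
        snapshots=_to_sequence(present, pairs, spec),
        strong_set=frozenset(),
        activities_true={i: float(a[i]) for i in range(spec.n_nodes)},
        spec=spec,
    )


def generate_benchmark(spec: SyntheticSpec, activities=None) -> SyntheticResult:
    """Null layer plus planted strong ties with known ground truth.

    Strong pairs are sampled uniformly among pairs with at least one null
    interaction; each gains an extra Bernoulli(boost) interaction per
    interval, OR-ed with the null event.
    """
    rng_act, rng_null, rng_sel, rng_boost = _substreams(spec.seed)
    a, pairs, present = _null_presence(spec, rng_act, rng_null, activities)
    interacting = np.flatnonzero(present.any(axis=0))
    n_strong = int(round(spec.strong_fraction * interacting.size))
    if spec.strong_fraction > 0 and n_strong < 1:
        warnings.warn("strong_fraction times interacting pairs is below 1; empty strong set",
                      stacklevel=2)
    strong_idx = (
        rng_sel.choice(interacting, size=n_strong, replace=False)
        if n_strong
        else np.array([], dtype=int)
    )
    if strong_idx.size:
        extra = rng_boost.random((spec.tau, strong_idx.size)) < spec.boost
        present[:, strong_idx] |= extra
    return SyntheticResult(
        snapshots=_to_sequence(present, pairs, spec),
        strong_set=frozenset(pairs[q] for q in strong_idx.tolist()),
        activities_true={i: float(a[i]) for i in range(spec.n_nodes)},
        spec=spec,
    )


def detection_rates(backbone_pairs: Iterable, strong_set: Iterable,
                    all_tested_pairs: Iterable):
    """(TPR, FPR, detected fraction) of a backbone against a planted strong set.

    TPR = recovered strong pairs / strong pairs (None when no strong pairs);
    FPR = flagged non-strong pairs / tested non-strong pairs;
    detected fraction = flagged pairs / tested pairs.
    """
    backbone = set(backbone_pairs)
    strong = set(strong_set)
    tested = set(all_tested_pairs)
    tpr = len(backbone & strong) / len(strong) if strong else None
    negatives = tested - strong
    fpr = len(backbone - strong) / len(negatives) if negatives else 0.0
    fraction = len(backbone) / len(tested) if tested else 0.0
    return tpr, fpr, fraction
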