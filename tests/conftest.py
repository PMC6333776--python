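"""Shared fixtures: tiny hand-checkable networks built in memory."""

import numpy as np
import pytest

from sigtie import AggregateCounts, SnapshotSequence


@pytest.fixture
def triangle_counts():
    """Saturated 3-node system: products a_i a_j = m_ij / tau are exact."""
    return AggregateCounts(
        counts={(0, 1): 2, (0, 2): 8, (1, 2): 4}, tau=16, node_universe=(0, 1, 2)
    )


@pytest.fixture
def symmetric4_counts():
    """4 nodes, all pair counts equal: symmetric solution a = sqrt(m/tau)."""
    pairs = {(i, j): 4 for i in range(4) for j in range(i + 1, 4)}
    return AggregateCounts(counts=pairs, tau=10, node_universe=tuple(range(4)))


def make_snapshots(snaps, nodes=None, delta=1.0):
    """Build a SnapshotSequence from a list of pair collections."""
    frozen = tuple(frozenset(tuple(sorted(p)) for p in snap) for snap in snaps)
    if nodes is None:
        seen = {}
        for s in frozen:
            for i, j in s:
                seen.setdefault(i)
                seen.setdefault(j)
        nodes = tuple(seen)
    return SnapshotSequence(snapshots=frozen, node_universe=tuple(nodes), delta=delta)


def null_counts(activities, tau, rng):
    """Directly draw Binomial(tau, a_i a_j) pair counts from the fitness null."""
    a = np.asarray(activities, dtype=float)
    n = a.size
    iu = np.triu_indices(n, k=1)
    u = (a[:, None] * a[None, :])[iu]
    m = rng.binomial(tau, u)
    counts = {
        (int(i), int(j)): int(k) for i, j, k in zip(iu[0], iu[1], m) if k > 0
    }
    return AggregateCounts(counts=counts, tau=tau, node_universe=tuple(range(n)))
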