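"""Timestamped interaction events, snapshot sequences and aggregate networks.

A temporal contact data set is a multiset of undirected interaction events
``(time, i, j)``.  Fixing a temporal resolution ``delta`` turns it into a
sequence of ``tau`` binary snapshots: the pair (i, j) is present in interval
``(t - delta, t]`` if it interacted at least once during that interval.
Summing snapshot presence over the ``tau`` intervals gives the aggregate
weighted network whose edge weights are the per-pair interaction counts
``m_ij`` in ``[0, tau]``.  These three representations (:class:`EventStream`,
:class:`SnapshotSequence`, :class:`AggregateCounts`) are the observation
units of every statistic in this package.

Observation sessions (e.g. school days) may leave long gaps with no
recording; intervals falling in such gaps are excluded from ``tau`` so that
the null model is only asked to explain time during which interactions could
actually be observed.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EventStream",
    "SnapshotSequence",
    "AggregateCounts",
    "Partition",
    "canonical_pair",
    "canonical_triple",
    "event_stream",
    "read_event_list",
    "write_event_list",
    "binarize_events",
    "aggregate_counts",
    "weighted_snapshots",
    "read_snapshots",
    "write_snapshots",
    "read_aggregate",
    "write_aggregate",
    "read_partition",
    "write_partition",
    "MalformedRecordError",
    "SelfLoopError",
]

Node = Hashable
Pair = tuple


class MalformedRecordError(ValueError):
    """A line of an event file did not parse to ``time i j``."""


class SelfLoopError(ValueError):
    """A record connects a node to itself; self-interactions are rejected."""


def canonical_pair(i: Node, j: Node) -> Pair:
    """Return the undirected pair (i, j) in canonical order.

    (i, j) and (j, i) denote the same tie, so every container in this package
    stores pairs canonically.  Nodes of mixed, non-comparable types are
    ordered by ``repr`` — any fixed total order works, it only has to be
    consistent.
    """
    if i == j:
        raise SelfLoopError(f"self-interaction on node {i!r} is not allowed")
    try:
        lo, hi = sorted((i, j))
    except TypeError:
        lo, hi = sorted((i, j), key=repr)
    return (lo, hi)


def canonical_triple(i: Node, j: Node, k: Node) -> tuple:
    """Canonically ordered triple of three distinct nodes."""
    if len({i, j, k}) != 3:
        raise ValueError(f"degenerate triple ({i!r}, {j!r}, {k!r})")
    try:
        return tuple(sorted((i, j, k)))
    except TypeError:
        return tuple(sorted((i, j, k), key=repr))


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventStream:
    """A multiset of timestamped undirected interaction events.

    Parameters
    ----------
    records
        Tuples ``(time, i, j)`` with ``i != j``.  Order is irrelevant;
        duplicates are meaningful (repeated interactions).
    node_universe
        Ordered tuple of node ids.  Defaults to the nodes observed in the
        records; may be extended with isolated nodes via an explicit list.
    """

    records: tuple
    node_universe: tuple

    @property
    def n_nodes(self) -> int:
        return len(self.node_universe)

    @property
    def time_span(self) -> tuple:
        """``(t_min, t_max)`` over the records; ``(nan, nan)`` if empty."""
        if not self.records:
            return (math.nan, math.nan)
        times = [t for t, _, _ in self.records]
        return (min(times), max(times))


def event_stream(records: Iterable[tuple], nodes: Iterable[Node] | None = None) -> EventStream:
    """Validate and build an :class:`EventStream`.

    Directed inputs are symmetrized: each record's pair is canonicalized, so
    (t, j, i) and (t, i, j) are the same event.
    """
    recs = []
    observed: dict[Node, None] = {}
    for rec in records:
        t, i, j = rec
        i, j = canonical_pair(i, j)
        observed.setdefault(i)
        observed.setdefault(j)
        recs.append((t, i, j))
    if nodes is not None:
        universe = tuple(dict.fromkeys(nodes))
        missing = [n for n in observed if n not in set(universe)]
        if missing:
            raise ValueError(f"records mention nodes outside the explicit node list: {missing[:5]}")
    else:
        universe = tuple(observed)
    return EventStream(records=tuple(recs), node_universe=universe)


@dataclass(frozen=True)
class SnapshotSequence:
    """Per-interval binary undirected edge sets at resolution ``delta``.

    ``snapshots[k]`` is the frozenset of canonical pairs interacting at least
    once in interval ``k``.  ``session_mask[k]`` is False for intervals that
    fall outside observation sessions; masked intervals never enter ``tau``
    or any count.
    """

    snapshots: tuple
    node_universe: tuple
    delta: float
    session_mask: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.session_mask is None:
            object.__setattr__(self, "session_mask", tuple(True for _ in self.snapshots))
        if len(self.session_mask) != len(self.snapshots):
            raise ValueError("session_mask length must match number of snapshots")
        universe = set(self.node_universe)
        for snap in self.snapshots:
            for i, j in snap:
                if i not in universe or j not in universe:
                    raise ValueError(f"pair ({i!r}, {j!r}) has an endpoint outside node_universe")

    @property
    def tau(self) -> int:
        """Number of unmasked intervals; the ``n`` of every binomial test."""
        return int(sum(self.session_mask))

    @property
    def n_nodes(self) -> int:
        return len(self.node_universe)

    def active_snapshots(self):
        """Iterate over the unmasked snapshots."""
        for snap, keep in zip(self.snapshots, self.session_mask):
            if keep:
                yield snap


@dataclass(frozen=True)
class AggregateCounts:
    """Aggregate weighted network: per-pair interaction counts over ``tau`` intervals.

    ``counts`` maps canonical pairs to integers in ``[0, tau]``; pairs absent
    from the mapping have count zero.  Node strength is the row sum of the
    weighted adjacency, degree the number of interacting partners.
    """

    counts: Mapping[Pair, int]
    tau: int
    node_universe: tuple

    def __post_init__(self):
        universe = set(self.node_universe)
        for (i, j), m in self.counts.items():
            if i not in universe or j not in universe:
                raise ValueError(f"pair ({i!r}, {j!r}) outside node_universe")
            if not (0 <= m <= self.tau):
                raise ValueError(f"count m({i!r},{j!r})={m} outside [0, tau={self.tau}]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_universe)

    @property
    def pairs(self) -> set:
        """Pairs with at least one interaction (the aggregate edges)."""
        return {p for p, m in self.counts.items() if m > 0}

    def weight(self, i: Node, j: Node) -> int:
        return self.counts.get(canonical_pair(i, j), 0)

    @property
    def strengths(self) -> dict:
        s = {n: 0 for n in self.node_universe}
        for (i, j), m in self.counts.items():
            s[i] += m
            s[j] += m
        return s

    @property
    def degrees(self) -> dict:
        d = {n: 0 for n in self.node_universe}
        for (i, j), m in self.counts.items():
            if m > 0:
                d[i] += 1
                d[j] += 1
        return d

    @property
    def total_weight(self) -> int:
        return sum(self.counts.values())

    def to_matrix(self, order: Sequence[Node] | None = None) -> np.ndarray:
        """Dense symmetric count matrix in the given (or universe) node order."""
        nodes = list(order) if order is not None else list(self.node_universe)
        index = {n: k for k, n in enumerate(nodes)}
        M = np.zeros((len(nodes), len(nodes)))
        for (i, j), m in self.counts.items():
            a, b = index[i], index[j]
            M[a, b] = M[b, a] = m
        return M


@dataclass(frozen=True)
class Partition:
    """Node -> group label map covering the whole node universe."""

    membership: Mapping[Node, Hashable]

    @property
    def groups(self) -> set:
        return set(self.membership.values())

    def label(self, node: Node) -> Hashable:
        try:
            return self.membership[node]
        except KeyError:
            raise KeyError(f"node {node!r} has no group label") from None

    def same_group(self, i: Node, j: Node) -> bool:
        return self.label(i) == self.label(j)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

_EPOCH_LIKE = 1e8  # timestamps above this are treated as epoch seconds
_DAY = 86400.0


def _infer_sessions(times: Sequence[float]) -> list[tuple]:
    """Default sessions: one per calendar day for epoch-like timestamps.

    This mirrors the usual practice with wearable-sensor deployments of
    excluding the overnight gap between the last contact of a day and the
    first contact of the next.  For small/abstract timestamps a single
    session covering the whole span is used.
    """
    t_min, t_max = min(times), max(times)
    if t_min < _EPOCH_LIKE:
        return [(t_min, t_max)]
    by_day: dict[int, list] = {}
    for t in times:
        by_day.setdefault(int(t // _DAY), []).append(t)
    return [(min(v), max(v)) for _, v in sorted(by_day.items())]


def _interval_index(t: float, start: float, delta: float, n_intervals: int) -> int:
    """Index of t within half-open intervals (start + k*delta, start + (k+1)*delta].

    Events at exactly the session start join interval 0.  Returns -1 when t
    falls beyond the last complete interval (trailing remainder).
    """
    if t == start:
        return 0
    k = math.ceil((t - start) / delta) - 1
    if k >= n_intervals:
        return -1
    return k


def binarize_events(
    events: EventStream,
    delta: float,
    sessions: Sequence[Sequence[float]] | None = None,
) -> SnapshotSequence:
    """Bin events into ``tau`` binary snapshots at resolution ``delta``.

    Intervals are half-open ``(t - delta, t]`` anchored at each session start;
    a trailing partial interval is dropped, so a session of span S contributes
    ``floor(S / delta)`` intervals and ``tau`` is their total.  Multiple
    events of a pair within one interval collapse to a single presence.

    Parameters
    ----------
    events
        The event stream.
    delta
        Interval width in the units of the timestamps; must be positive and
        no larger than the covered span.
    sessions
        Optional non-overlapping ``[start, end]`` observation windows.  When
        omitted, epoch-like data gets one session per calendar day (day-gap
        exclusion) and other data one session over the whole span.  Events
        outside all sessions are dropped with a warning.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if not events.records and sessions is None:
        raise ValueError("cannot binarize an empty event stream without explicit sessions")

    if sessions is None:
        sess = _infer_sessions([t for t, _, _ in events.records])
    else:
        sess = [(float(s), float(e)) for s, e in sessions]
        for (s, e) in sess:
            if e < s:
                raise ValueError(f"session ({s}, {e}) has end before start")
        sess.sort()
        for (s1, e1), (s2, e2) in zip(sess, sess[1:]):
            if s2 < e1:
                raise ValueError("sessions must be non-overlapping")

    n_per_session = [int(math.floor((e - s) / delta)) for s, e in sess]
    tau = sum(n_per_session)
    if tau == 0:
        raise ValueError(
            f"delta={delta} is larger than the covered session span; no complete interval fits"
        )
    offsets = np.concatenate([[0], np.cumsum(n_per_session)])[:-1]

    snapshots: list[set] = [set() for _ in range(tau)]
    n_dropped = 0
    for t, i, j in events.records:
        placed = False
        for (start, end), n_k, off in zip(sess, n_per_session, offsets):
            if start <= t <= end:
                k = _interval_index(t, start, delta, n_k)
                if k >= 0:
                    snapshots[int(off) + k].add(canonical_pair(i, j))
                    placed = True
                break
        if not placed:
            n_dropped += 1
    if n_dropped:
        warnings.warn(
            f"{n_dropped} event(s) outside all sessions or in a trailing partial interval "
            "were dropped",
            stacklevel=2,
        )

    return SnapshotSequence(
        snapshots=tuple(frozenset(s) for s in snapshots),
        node_universe=events.node_universe,
        delta=float(delta),
        session_mask=tuple(True for _ in range(tau)),
    )


def aggregate_counts(snapshots: SnapshotSequence) -> AggregateCounts:
    """Aggregate a snapshot sequence into per-pair counts m_ij over unmasked intervals."""
    counter: Counter = Counter()
    for snap in snapshots.active_snapshots():
        counter.update(snap)
    return AggregateCounts(
        counts=dict(counter),
        tau=snapshots.tau,
        node_universe=snapshots.node_universe,
    )


def weighted_snapshots(
    events: EventStream,
    delta: float,
    sessions: Sequence[Sequence[float]] | None = None,
) -> list[AggregateCounts]:
    """Per-interval weighted networks: edge weight = number of events in the window.

    This is the input format of the snapshot-repeated disparity filter; unlike
    :func:`binarize_events` multiplicity within an interval is kept.
    Each element has ``tau = 1`` semantics (one observation window).
    """
    binary = binarize_events(events, delta, sessions)  # reuse validation/session logic
    # Re-run the assignment keeping multiplicity.
    if sessions is None:
        sess = _infer_sessions([t for t, _, _ in events.records])
    else:
        sess = sorted((float(s), float(e)) for s, e in sessions)
    n_per_session = [int(math.floor((e - s) / delta)) for s, e in sess]
    offsets = np.concatenate([[0], np.cumsum(n_per_session)])[:-1]
    counters: list[Counter] = [Counter() for _ in range(binary.tau)]
    for t, i, j in events.records:
        for (start, end), n_k, off in zip(sess, n_per_session, offsets):
            if start <= t <= end:
                k = _interval_index(t, start, delta, n_k)
                if k >= 0:
                    counters[int(off) + k][canonical_pair(i, j)] += 1
                break
    return [
        AggregateCounts(
            counts=dict(c),
            tau=max(c.values(), default=1),
            node_universe=events.node_universe,
        )
        for c in counters
    ]


def snapshot_weights(snapshots: SnapshotSequence) -> list[AggregateCounts]:
    """View a binary snapshot sequence as unit-weight per-interval networks."""
    return [
        AggregateCounts(counts={p: 1 for p in snap}, tau=1, node_universe=snapshots.node_universe)
        for snap in snapshots.active_snapshots()
    ]


# ---------------------------------------------------------------------------
# I/O: whitespace-separated text formats
# ---------------------------------------------------------------------------


def _parse_node(token: str) -> Node:
    # digit-only ids become ints so written/read streams round-trip
    if token.lstrip("-").isdigit():
        return int(token)
    return token


def read_event_list(
    path: str | Path,
    dialect: str = "sociopatterns",
    nodes: Iterable[Node] | None = None,
) -> EventStream:
    """Read a whitespace/tab-separated event list ``t i j``.

    The SocioPatterns dialect is plain ``t i j`` with integer epoch seconds on
    a 20-s grid; any numeric timestamp parses.  Directed records are
    symmetrized.  Self-loop records and malformed lines raise with the
    offending line number.
    """
    if dialect not in ("sociopatterns", "tij"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise MalformedRecordError(f"{path}:{lineno}: expected 't i j', got {line!r}")
            try:
                t = float(parts[0])
            except ValueError:
                raise MalformedRecordError(
                    f"{path}:{lineno}: non-numeric timestamp {parts[0]!r}"
                ) from None
            i, j = _parse_node(parts[1]), _parse_node(parts[2])
            if i == j:
                raise SelfLoopError(f"{path}:{lineno}: self-interaction on node {i!r}")
            records.append((t, i, j))
    return event_stream(records, nodes=nodes)


def write_event_list(events: EventStream, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t, i, j in events.records:
            t_repr = int(t) if float(t).is_integer() else t
            fh.write(f"{t_repr}\t{i}\t{j}\n")


def write_snapshots(snapshots: SnapshotSequence, path: str | Path) -> None:
    """Serialize as ``interval_index i j`` records (unmasked intervals only)."""
    with Path(path).open("w") as fh:
        k = 0
        for snap in snapshots.active_snapshots():
            for i, j in sorted(snap, key=repr):
                fh.write(f"{k}\t{i}\t{j}\n")
            k += 1


def read_snapshots(
    path: str | Path,
    delta: float = 1.0,
    tau: int | None = None,
    nodes: Iterable[Node] | None = None,
) -> SnapshotSequence:
    """Read ``interval_index i j`` records back into a :class:`SnapshotSequence`.

    ``tau`` may exceed the largest index on file (trailing empty snapshots).
    """
    per_interval: dict[int, set] = {}
    max_k = -1
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise MalformedRecordError(f"{path}:{lineno}: expected 'k i j', got {line!r}")
            k = int(parts[0])
            i, j = _parse_node(parts[1]), _parse_node(parts[2])
            per_interval.setdefault(k, set()).add(canonical_pair(i, j))
            max_k = max(max_k, k)
    n = tau if tau is not None else max_k + 1
    if n <= max_k:
        raise ValueError(f"tau={n} smaller than largest interval index {max_k} on file")
    observed: dict[Node, None] = {}
    for snap in per_interval.values():
        for i, j in snap:
            observed.setdefault(i)
            observed.setdefault(j)
    universe = tuple(dict.fromkeys(nodes)) if nodes is not None else tuple(observed)
    return SnapshotSequence(
        snapshots=tuple(frozenset(per_interval.get(k, set())) for k in range(n)),
        node_universe=universe,
        delta=float(delta),
    )


def write_aggregate(counts: AggregateCounts, path: str | Path) -> None:
    """Weighted edge list ``i j m_obs`` (interacting pairs only)."""
    with Path(path).open("w") as fh:
        fh.write(f"# tau={counts.tau}\n")
        for (i, j), m in sorted(counts.counts.items(), key=repr):
            if m > 0:
                fh.write(f"{i}\t{j}\t{m}\n")


def read_aggregate(path: str | Path, tau: int | None = None,
                   nodes: Iterable[Node] | None = None) -> AggregateCounts:
    counts: dict = {}
    file_tau = None
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("#"):
                if "tau=" in line:
                    file_tau = int(line.split("tau=")[1])
                continue
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise MalformedRecordError(f"{path}:{lineno}: expected 'i j m', got {line!r}")
            i, j = _parse_node(parts[0]), _parse_node(parts[1])
            counts[canonical_pair(i, j)] = int(parts[2])
    if tau is None:
        tau = file_tau if file_tau is not None else max(counts.values(), default=0)
    observed: dict[Node, None] = {}
    for i, j in counts:
        observed.setdefault(i)
        observed.setdefault(j)
    universe = tuple(dict.fromkeys(nodes)) if nodes is not None else tuple(observed)
    return AggregateCounts(counts=counts, tau=tau, node_universe=universe)


def read_partition(path: str | Path) -> Partition:
    """Read a ``node<TAB>group`` table."""
    membership: dict = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise MalformedRecordError(f"{path}:{lineno}: expected 'node group', got {line!r}")
            membership[_parse_node(parts[0])] = parts[1]
    return Partition(membership=membership)


def write_partition(partition: Partition, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for node, group in sorted(partition.membership.items(), key=repr):
            fh.write(f"{node}\t{group}\n")
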