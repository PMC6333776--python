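"""Event parsing, snapshot binning and aggregation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigtie import (
    aggregate_counts,
    binarize_events,
    canonical_pair,
    event_stream,
    read_event_list,
)
from sigtie.temporal import (
    MalformedRecordError,
    SelfLoopError,
    read_aggregate,
    read_partition,
    read_snapshots,
    snapshot_weights,
    weighted_snapshots,
    write_aggregate,
    write_event_list,
    write_partition,
    write_snapshots,
)

from conftest import make_snapshots


class TestReadEventList:
    def test_parses_t_i_j_records(self, tmp_path):
        f = tmp_path / "ev.tsv"
        f.write_text("20 A B\n40 A B\n40 B C\n")
        ev = read_event_list(f)
        assert len(ev.records) == 3
        assert set(ev.node_universe) == {"A", "B", "C"}
        assert ev.time_span == (20.0, 40.0)

    def test_empty_file_with_explicit_nodes(self, tmp_path):
        f = tmp_path / "ev.tsv"
        f.write_text("")
        ev = read_event_list(f, nodes=["a", "b", "c", "d", "e"])
        assert len(ev.records) == 0
        assert ev.n_nodes == 5

    def test_self_loop_rejected(self, tmp_path):
        f = tmp_path / "ev.tsv"
        f.write_text("20 A A\n")
        with pytest.raises(SelfLoopError):
            read_event_list(f)

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "ev.tsv"
        f.write_text("20 A B\nnot-a-line\n")
        with pytest.raises(MalformedRecordError, match=":2"):
            read_event_list(f)

    def test_directed_records_symmetrized(self, tmp_path):
        f = tmp_path / "ev.tsv"
        f.write_text("1 B A\n2 A B\n")
        ev = read_event_list(f)
        assert {canonical_pair(i, j) for _, i, j in ev.records} == {("A", "B")}

    def test_duplicate_records_preserved(self, tmp_path):
        f = tmp_path / "ev.tsv"
        f.write_text("20 A B\n20 A B\n")
        assert len(read_event_list(f).records) == 2


class TestBinarize:
    def test_hand_binning_two_intervals(self):
        ev = event_stream([(5, "A", "B"), (12, "A", "B")])
        snaps = binarize_events(ev, delta=10, sessions=[(0, 20)])
        assert snaps.tau == 2
        assert all(("A", "B") in s for s in snaps.snapshots)
        assert aggregate_counts(snaps).counts[("A", "B")] == 2

    def test_same_interval_collapses(self):
        ev = event_stream([(5, "A", "B"), (7, "A", "B")])
        snaps = binarize_events(ev, delta=10, sessions=[(0, 10)])
        assert snaps.tau == 1
        assert aggregate_counts(snaps).counts[("A", "B")] == 1

    def test_session_gap_excluded_from_tau(self):
        ev = event_stream([(5, "A", "B"), (1005, "A", "B")])
        snaps = binarize_events(ev, delta=10, sessions=[(0, 100), (1000, 1100)])
        assert snaps.tau == 20  # the 900-unit gap contributes no intervals

    def test_delta_larger_than_span_errors(self):
        ev = event_stream([(5, "A", "B"), (12, "A", "B")])
        with pytest.raises(ValueError, match="larger than"):
            binarize_events(ev, delta=100, sessions=[(0, 20)])

    def test_out_of_session_events_warn_and_drop(self):
        ev = event_stream([(5, "A", "B"), (500, "A", "C")])
        with pytest.warns(UserWarning, match="dropped"):
            snaps = binarize_events(ev, delta=10, sessions=[(0, 20)])
        assert ("A", "C") not in aggregate_counts(snaps).pairs

    def test_epoch_timestamps_get_daily_sessions(self):
        # two calendar days of epoch-second data; overnight gap excluded
        day = 86400
        t0 = 1_500_000_000 - (1_500_000_000 % day)
        ev = event_stream(
            [(t0 + 100, "A", "B"), (t0 + 500, "A", "B"),
             (t0 + day + 100, "A", "B"), (t0 + day + 300, "B", "C")]
        )
        snaps = binarize_events(ev, delta=20)
        # day 1 span 400 -> 20 intervals; day 2 span 200 -> 10 intervals
        assert snaps.tau == 30

    def test_overlapping_sessions_rejected(self):
        ev = event_stream([(5, "A", "B")])
        with pytest.raises(ValueError, match="non-overlapping"):
            binarize_events(ev, delta=1, sessions=[(0, 10), (5, 15)])


class TestAggregate:
    def test_counting_and_node_stats(self):
        snaps = make_snapshots(
            [[("A", "B")], [("A", "B")], [("A", "B")], [], []]
        )
        agg = aggregate_counts(snaps)
        assert agg.counts[("A", "B")] == 3
        assert agg.degrees["A"] == 1
        assert agg.strengths["A"] == 3

    def test_empty_sequence(self):
        snaps = make_snapshots([[], []], nodes=("A", "B"))
        agg = aggregate_counts(snaps)
        assert agg.total_weight == 0

    def test_full_triangle_strengths(self):
        tri = [("A", "B"), ("B", "C"), ("A", "C")]
        snaps = make_snapshots([tri] * 4)
        agg = aggregate_counts(snaps)
        assert all(m == 4 for m in agg.counts.values())
        assert all(s == 8 for s in agg.strengths.values())

    def test_degree_sum_is_twice_edge_count(self):
        snaps = make_snapshots([[("A", "B"), ("C", "D")], [("A", "C")]])
        agg = aggregate_counts(snaps)
        assert sum(agg.degrees.values()) == 2 * len(agg.pairs)

    def test_masked_intervals_excluded(self):
        from sigtie import SnapshotSequence

        snaps = SnapshotSequence(
            snapshots=(frozenset({("A", "B")}), frozenset({("A", "B")})),
            node_universe=("A", "B"),
            delta=1.0,
            session_mask=(True, False),
        )
        assert snaps.tau == 1
        assert aggregate_counts(snaps).counts[("A", "B")] == 1


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    events=st.lists(
        st.tuples(
            st.floats(min_value=0.01, max_value=99.9),
            st.sampled_from("ABCDE"),
            st.sampled_from("ABCDE"),
        ).filter(lambda r: r[1] != r[2]),
        min_size=1,
        max_size=30,
    ),
    seed=st.integers(0, 100),
)
def test_aggregation_invariant_under_record_order_and_pair_swap(events, seed):
    """Counts depend only on the event multiset, not order or pair orientation."""
    import random

    ev1 = event_stream(events)
    shuffled = events[:]
    random.Random(seed).shuffle(shuffled)
    swapped = [(t, j, i) for (t, i, j) in shuffled]
    ev2 = event_stream(swapped)
    a1 = aggregate_counts(binarize_events(ev1, delta=10, sessions=[(0, 100)]))
    a2 = aggregate_counts(binarize_events(ev2, delta=10, sessions=[(0, 100)]))
    assert a1.counts == a2.counts
    assert a1.tau == a2.tau


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    times=st.lists(st.floats(min_value=0.01, max_value=119.9), min_size=1, max_size=40),
    k=st.integers(2, 5),
)
def test_coarser_bins_never_increase_counts(times, k):
    """For delta' = k*delta aligned at the session start, m_obs can only shrink."""
    ev = event_stream([(t, "A", "B") for t in times])
    fine = aggregate_counts(binarize_events(ev, delta=1, sessions=[(0, 120)]))
    coarse = aggregate_counts(binarize_events(ev, delta=k, sessions=[(0, 120)]))
    assert coarse.counts.get(("A", "B"), 0) <= fine.counts.get(("A", "B"), 0)
    assert fine.counts.get(("A", "B"), 0) <= fine.tau


class TestRoundTrips:
    def test_event_list(self, tmp_path):
        ev = event_stream([(20, 1, 2), (40, 2, 3)])
        write_event_list(ev, tmp_path / "e.tsv")
        back = read_event_list(tmp_path / "e.tsv")
        assert back.records == ev.records

    def test_snapshots(self, tmp_path):
        snaps = make_snapshots([[(1, 2)], [], [(1, 2), (2, 3)]])
        write_snapshots(snaps, tmp_path / "s.tsv")
        back = read_snapshots(tmp_path / "s.tsv", tau=3)
        assert back.snapshots == snaps.snapshots

    def test_aggregate(self, tmp_path):
        snaps = make_snapshots([[(1, 2)], [(1, 2), (2, 3)]])
        agg = aggregate_counts(snaps)
        write_aggregate(agg, tmp_path / "a.tsv")
        back = read_aggregate(tmp_path / "a.tsv")
        assert back.counts == agg.counts
        assert back.tau == agg.tau

    def test_partition(self, tmp_path):
        from sigtie import Partition

        part = Partition(membership={1: "x", 2: "x", 3: "y"})
        write_partition(part, tmp_path / "p.tsv")
        back = read_partition(tmp_path / "p.tsv")
        assert back.membership == {1: "x", 2: "x", 3: "y"}


def test_weighted_snapshots_keep_multiplicity():
    ev = event_stream([(1, "A", "B"), (2, "A", "B"), (12, "A", "B")])
    ws = weighted_snapshots(ev, delta=10, sessions=[(0, 20)])
    assert len(ws) == 2
    assert ws[0].counts[("A", "B")] == 2
    assert ws[1].counts[("A", "B")] == 1


def test_snapshot_weights_are_unit():
    snaps = make_snapshots([[("A", "B"), ("B", "C")], [("A", "B")]])
    ws = snapshot_weights(snaps)
    assert [w.counts for w in ws] == [
        {("A", "B"): 1, ("B", "C"): 1},
        {("A", "B"): 1},
    ]
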