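"""Tie and triad significance: binomial kernel, decision rules, backbones."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigtie import (
    AggregateCounts,
    SignificantTieFilter,
    binomial_upper_pvalue,
    count_simultaneous_triads,
)
from sigtie import test_ties as run_tie_tests
from sigtie import test_triads as run_triad_tests
from sigtie.significance import aggregate_triangles

from conftest import make_snapshots, null_counts


def brute_force_upper_tail(p, tau, x_obs):
    """Independent oracle: direct summation of the binomial pmf above x_obs."""
    return sum(
        math.comb(tau, k) * p**k * (1 - p) ** (tau - k) for k in range(x_obs + 1, tau + 1)
    )


class TestBinomialKernel:
    def test_half_probability_four_trials(self):
        # only X=4 of the 16 equally likely outcomes exceeds 3
        assert binomial_upper_pvalue(0.5, 4, 3) == pytest.approx(0.0625, abs=1e-12)

    def test_observed_equals_tau_gives_zero(self):
        assert binomial_upper_pvalue(0.37, 12, 12) == 0.0

    def test_complement_of_zero_successes(self):
        assert binomial_upper_pvalue(0.1, 2, 0) == pytest.approx(0.19, abs=1e-12)

    def test_x_above_tau_rejected(self):
        with pytest.raises(ValueError):
            binomial_upper_pvalue(0.5, 4, 5)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        p=st.floats(min_value=0.01, max_value=0.99),
        tau=st.integers(1, 20),
        data=st.data(),
    )
    def test_matches_brute_force_summation(self, p, tau, data):
        x = data.draw(st.integers(0, tau))
        assert binomial_upper_pvalue(p, tau, x) == pytest.approx(
            brute_force_upper_tail(p, tau, x), abs=1e-12
        )


def _uniform_counts(ms, tau):
    """Counts over disjoint pairs (2q, 2q+1) with given m values."""
    counts = {(2 * q, 2 * q + 1): m for q, m in enumerate(ms)}
    nodes = tuple(range(2 * len(ms)))
    return AggregateCounts(counts=counts, tau=tau, node_universe=nodes)


class TestTieDecisionRules:
    """u = 0.5 for every pair, tau = 4: the lattice where the rules differ."""

    def setup_method(self):
        self.counts = _uniform_counts([4, 3, 1], tau=4)
        a = math.sqrt(0.5)
        self.act = {n: a for n in self.counts.node_universe}

    def test_strict_pvalue_rule_flags_the_top_lattice_point(self):
        bb = run_tie_tests(self.counts, self.act, alpha=0.05, decision="pvalue")
        by_m = {t.m_obs: t for t in bb.tests}
        assert by_m[4].p_value == pytest.approx(0.0)
        assert by_m[4].significant
        assert by_m[3].p_value == pytest.approx(0.0625, abs=1e-9)
        assert not by_m[3].significant

    def test_percentile_rule_respects_the_level(self):
        # P(X >= 4) = 0.0625 > 0.05: even a saturated count is explainable
        bb = run_tie_tests(self.counts, self.act, alpha=0.05, decision="percentile")
        assert not any(t.significant for t in bb.tests)
        # but at alpha = 0.07 the saturated pair clears the percentile
        bb7 = bb.at(0.07)
        assert {t.m_obs for t in bb7.ties} == {4}

    def test_p_ge_exceeds_p_value_by_pmf_at_observation(self):
        bb = run_tie_tests(self.counts, self.act, alpha=0.05)
        for t in bb.tests:
            pmf = math.comb(4, t.m_obs) * 0.5**4
            assert t.p_ge == pytest.approx(t.p_value + pmf, rel=1e-9)


class TestBackbone:
    def test_only_interacting_pairs_tested(self):
        counts = _uniform_counts([3, 0], tau=5)
        act = {n: 0.5 for n in counts.node_universe}
        bb = run_tie_tests(counts, act, alpha=0.1)
        assert {t.pair for t in bb.tests} == {(0, 1)}

    def test_bonferroni_divides_by_n_tested(self):
        counts = _uniform_counts([2, 2, 2, 2, 2], tau=5)
        act = {n: 0.5 for n in counts.node_universe}
        bb = run_tie_tests(counts, act, alpha=0.05, bonferroni=True)
        assert bb.n_tested == 5
        assert bb.alpha_effective == pytest.approx(0.01)

    def test_nesting_in_alpha(self):
        rng = np.random.default_rng(0)
        counts = null_counts(rng.beta(2, 2, size=15), tau=40, rng=rng)
        act = {n: 0.4 for n in range(15)}
        bb = run_tie_tests(counts, act, alpha=0.5)
        for lo, hi in [(1e-6, 1e-2), (1e-3, 0.1), (0.01, 0.5)]:
            assert bb.at(lo).pairs <= bb.at(hi).pairs

    def test_alpha_out_of_range_rejected(self):
        counts = _uniform_counts([1], tau=2)
        with pytest.raises(ValueError):
            run_tie_tests(counts, {0: 0.5, 1: 0.5}, alpha=1.5)

    def test_filter_events_keeps_only_significant_pairs(self):
        from sigtie import event_stream

        counts = _uniform_counts([5, 1], tau=5)
        act = {n: 0.1 for n in counts.node_universe}
        bb = run_tie_tests(counts, act, alpha=0.01)
        assert bb.pairs == {(0, 1)}
        ev = event_stream([(1, 0, 1), (2, 1, 0), (3, 2, 3)])
        sub = bb.filter_events(ev)
        assert len(sub.records) == 2
        assert set(sub.node_universe) == {0, 1}


class TestSimultaneousTriads:
    def test_counts_full_co_occurrence_only(self):
        tri = [("A", "B"), ("B", "C"), ("A", "C")]
        snaps = make_snapshots([[], tri, [("A", "B")], tri, []])
        r = count_simultaneous_triads(snaps, [("A", "B", "C")])
        assert r[("A", "B", "C")] == 2

    def test_rotating_edges_never_simultaneous(self):
        snaps = make_snapshots([[("A", "B")], [("B", "C")], [("A", "C")]])
        r = count_simultaneous_triads(snaps, [("A", "B", "C")])
        assert r[("A", "B", "C")] == 0

    def test_empty_sequence(self):
        snaps = make_snapshots([[], []], nodes=("A", "B", "C"))
        assert count_simultaneous_triads(snaps, [("A", "B", "C")]) == {
            ("A", "B", "C"): 0
        }

    def test_degenerate_triple_rejected(self):
        snaps = make_snapshots([[("A", "B")]])
        with pytest.raises(ValueError, match="degenerate"):
            count_simultaneous_triads(snaps, [("A", "A", "B")])

    def test_deterministic_triangle_under_both_rules(self):
        tri = [("A", "B"), ("B", "C"), ("A", "C")]
        snaps = make_snapshots([tri] * 6)
        act = {"A": 1.0, "B": 1.0, "C": 1.0}
        strict = run_triad_tests(snaps, activities=act, alpha=0.01, decision="pvalue")[0]
        assert strict.v == pytest.approx(1.0)
        assert strict.p_value == 0.0
        assert strict.significant
        # under the percentile rule a null-certain event carries no surprise
        cons = run_triad_tests(snaps, activities=act, alpha=0.01)[0]
        assert not cons.significant

    def test_null_triangle_probability_is_product(self):
        tri = [("A", "B"), ("B", "C"), ("A", "C")]
        snaps = make_snapshots([tri, [], [], []])
        act = {n: 0.5 for n in "ABC"}
        tt = run_triad_tests(snaps, activities=act, alpha=0.5)[0]
        assert tt.v == pytest.approx(0.25**3, abs=1e-12)

    def test_zero_observed_never_significant(self):
        # aggregate triangle exists but edges never co-occur
        snaps = make_snapshots([[("A", "B")], [("B", "C")], [("A", "C")], []])
        act = {n: 0.5 for n in "ABC"}
        tt = run_triad_tests(snaps, activities=act, alpha=0.99, decision="pvalue")[0]
        assert tt.r_obs == 0
        assert tt.p_value == pytest.approx(1 - (1 - 0.015625) ** 4, rel=1e-9)
        assert not tt.significant

    def test_candidates_are_aggregate_triangles(self):
        snaps = make_snapshots(
            [[("A", "B"), ("C", "D")], [("B", "C")], [("A", "C")]]
        )
        from sigtie import aggregate_counts

        tris = aggregate_triangles(aggregate_counts(snaps))
        assert tris == [("A", "B", "C")]


class TestOrderDecoupling:
    """Dyad and triad significance are genuinely different orders of structure."""

    def test_significant_triad_with_no_significant_dyads(self):
        # three weak pairs that always co-occur: each count is individually
        # unremarkable, their simultaneity is wildly improbable
        tau = 100
        tri = [("A", "B"), ("B", "C"), ("A", "C")]
        snaps = make_snapshots([tri] * 3 + [[]] * (tau - 3))
        act = {n: 0.1 for n in "ABC"}  # u = 0.01, v = 1e-6
        tt = run_triad_tests(snaps, activities=act, alpha=0.01)[0]
        assert tt.significant
        assert tt.n_significant_dyads == 0

    def test_three_significant_dyads_without_significant_triad(self):
        # strong pairs that never interact simultaneously
        tau = 30
        cyc = [[("A", "B")], [("B", "C")], [("A", "C")]] * 10
        snaps = make_snapshots(cyc)
        act = {n: 0.1 for n in "ABC"}
        tt = run_triad_tests(snaps, activities=act, alpha=0.01)[0]
        assert tt.n_significant_dyads == 3
        assert not tt.significant


class TestSignificantTieFilterAPI:
    def test_fit_backbone_transform(self):
        from sigtie import SyntheticSpec, generate_benchmark

        res = generate_benchmark(SyntheticSpec(n_nodes=40, t_span=200, delta=5, seed=3))
        f = SignificantTieFilter(alpha=0.01).fit(res.snapshots)
        bb = f.backbone()
        assert bb.n_tested == len(f.tests_)
        assert bb.at(1e-5).pairs <= bb.pairs
        filtered = f.transform(res.snapshots)
        kept = set().union(*filtered.snapshots) if any(filtered.snapshots) else set()
        assert kept <= bb.pairs

    def test_supplied_activities_skip_estimation(self):
        counts = _uniform_counts([5, 1], tau=5)
        f = SignificantTieFilter(alpha=0.01).fit(
            counts, activities={n: 0.1 for n in counts.node_universe}
        )
        assert f.backbone().pairs == {(0, 1)}

    def test_sklearn_params(self):
        f = SignificantTieFilter(alpha=0.005, bonferroni=True)
        p = f.get_params()
        assert p["alpha"] == 0.005 and p["bonferroni"]
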