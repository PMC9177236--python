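"""Group statistics: counts, FDR, paired tests, Friedman, lesions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gango import (
    DegenerateDataError,
    DirectedConnectome,
    InputError,
    NetworkPartition,
    bh_fdr,
    friedman_nemenyi,
    global_efficiency,
    inter_rsn_tests,
    lesion_curve,
    random_directed_graph,
    rsn_counts,
    sender_receiver,
    single_node_lesions,
    targeted_attack,
)
from gango.metrics import centrality_table


class TestRsnCounts:
    def test_within_module_edges_on_diagonal(self, four_module_partition):
        g = DirectedConnectome(12, frozenset({(0, 1), (1, 2), (3, 4)}))
        c = rsn_counts(g, four_module_partition)
        assert c.loc["A", "A"] == 2 and c.loc["B", "B"] == 1
        assert c.to_numpy().sum() - np.trace(c.to_numpy()) == 0

    def test_single_cross_module_edge(self, four_module_partition):
        g = DirectedConnectome(12, frozenset({(0, 3)}))  # A -> B
        c = rsn_counts(g, four_module_partition)
        assert c.loc["A", "B"] == 1 and c.loc["B", "A"] == 0

    def test_conservation(self, four_module_partition):
        g = random_directed_graph(12, 50, seed=0)
        c = rsn_counts(g, four_module_partition)
        assert c.to_numpy().sum() == 50


class TestBhFdr:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_dominate_raw_and_capped(self, ps):
        adj = bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)


def _planted_cohort(n_subjects, seed, sender_frac=None, ab_frac=None):
    """Random 4-module cohorts on p=24, optionally planting structure.

    sender_frac: fraction of module-A nodes' edges forced outgoing.
    ab_frac: fraction of A<->B cross edges forced in the A->B direction.
    """
    rng = np.random.default_rng(seed)
    labels = tuple(np.repeat(["A", "B", "C", "D"], 6))
    part = NetworkPartition(labels)
    a_nodes = [i for i, lab in enumerate(labels) if lab == "A"]
    b_nodes = [i for i, lab in enumerate(labels) if lab == "B"]
    graphs = []
    for _ in range(n_subjects):
        edges = set()
        if ab_frac is not None:
            # plant an over-connected A-B pair with a preferred direction
            while len(edges) < 20:
                a = int(rng.choice(a_nodes))
                b = int(rng.choice(b_nodes))
                i, j = (a, b) if rng.random() < ab_frac else (b, a)
                if (j, i) not in edges:
                    edges.add((i, j))
        while len(edges) < 60:
            i, j = rng.integers(0, 24, 2)
            if i == j:
                continue
            if sender_frac is not None:
                # edges touching module A point away from A
                if labels[j] == "A" and labels[i] != "A" and rng.random() < sender_frac:
                    i, j = j, i
            if (j, i) not in edges:
                edges.add((int(i), int(j)))
        graphs.append(DirectedConnectome(24, frozenset(edges)))
    return part, graphs


class TestInterRsnTests:
    def test_too_few_subjects(self, four_module_partition):
        g = random_directed_graph(12, 30, seed=1)
        counts = [rsn_counts(g, four_module_partition)] * 2
        with pytest.raises(InputError):
            inter_rsn_tests(counts)

    def test_planted_direction_recovered(self):
        part, graphs = _planted_cohort(30, seed=2, ab_frac=0.9)
        counts = [rsn_counts(g, part) for g in graphs]
        res = inter_rsn_tests(counts)
        row = res[(res.module_a == "A") & (res.module_b == "B")].iloc[0]
        assert row.connected
        assert row.direction == "A->B"
        assert row.mean_prop_a_to_b == pytest.approx(0.9, abs=0.08)

    def test_uniform_null_mostly_unconnected_pairs(self):
        part, graphs = _planted_cohort(20, seed=3)
        counts = [rsn_counts(g, part) for g in graphs]
        res = inter_rsn_tests(counts)
        # uniform wiring: the equal-spread null holds, few/no pairs survive
        assert res.connected.sum() <= 1


class TestSenderReceiver:
    def test_planted_sender_recovered(self):
        part, graphs = _planted_cohort(25, seed=4, sender_frac=0.95)
        tables = [centrality_table(g) for g in graphs]
        res = sender_receiver(tables, part)
        assert res[res.module == "A"].classification.iloc[0] == "sender"

    def test_silent_module_balanced_with_flag(self):
        labels = tuple(np.repeat(["A", "B"], 4))
        part = NetworkPartition(labels)
        graphs = [
            DirectedConnectome(8, frozenset({(0, 1), (1, 2), (2, 3)}))
            for _ in range(8)
        ]  # module B has no edges at all
        tables = [centrality_table(g) for g in graphs]
        res = sender_receiver(tables, part)
        row = res[res.module == "B"].iloc[0]
        assert row.classification == "balanced" and row.degenerate

    def test_too_few_subjects(self, four_module_partition):
        tables = [centrality_table(random_directed_graph(12, 30, seed=5))] * 3
        with pytest.raises(InputError):
            sender_receiver(tables, four_module_partition)


class TestFriedmanNemenyi:
    def test_fully_tied_not_significant(self):
        rep = friedman_nemenyi(np.ones((12, 4)))
        assert rep["p_value"] == 1.0 and not rep["significant"]

    def test_textbook_chi_square_form(self):
        # closed form on untied ranks: chi2 = 12n/(k(k+1)) * sum(Rbar - (k+1)/2)^2
        rng = np.random.default_rng(6)
        x = rng.standard_normal((10, 3)) + np.array([0.0, 0.5, 1.0])
        rep = friedman_nemenyi(x)
        from scipy.stats import rankdata

        ranks = rankdata(x, axis=1)
        rbar = ranks.mean(axis=0)
        n, k = x.shape
        chi2 = 12 * n / (k * (k + 1)) * np.sum((rbar - (k + 1) / 2) ** 2)
        assert rep["statistic"] == pytest.approx(chi2)

    def test_planted_module_separates_in_posthoc(self):
        rng = np.random.default_rng(7)
        x = rng.normal(10, 1, (50, 4))
        x[:, 2] *= 2  # planted high-centrality module
        rep = friedman_nemenyi(x)
        assert rep["significant"]
        assert np.argmax(rep["mean_ranks"]) == 2
        others = [rep["posthoc_p"][2, j] for j in (0, 1, 3)]
        assert max(others) < 0.01


class TestLesions:
    def test_deleting_nothing_zero(self, path_graph):
        np.testing.assert_allclose(lesion_curve(path_graph, []), [0.0])

    def test_disconnected_node_gives_positive_change(self):
        g = DirectedConnectome(4, frozenset({(0, 1), (1, 2)}))
        curve = lesion_curve(g, [3])
        assert curve[-1] > 0

    def test_star_center_deletion_is_total_loss(self, star_graph):
        curve = lesion_curve(star_graph, [0])
        assert curve[-1] == pytest.approx(-100.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(DegenerateDataError):
            lesion_curve(DirectedConnectome(5), [0])

    def test_single_node_lesions_on_star(self, star_graph):
        deltas = single_node_lesions(star_graph)
        e0 = global_efficiency(star_graph)
        assert deltas[0] == pytest.approx(-e0)  # center removal kills all paths
        # deleting a leaf removes the distance-2 leaf pairs, which raises
        # the mean: E goes 0.70 -> 0.75 by hand enumeration
        np.testing.assert_allclose(deltas[1:], 0.05, atol=1e-12)

    def test_single_node_lesions_complete_graph(self):
        edges = {(i, j) for i in range(5) for j in range(5) if i != j}
        g = DirectedConnectome(5, frozenset(edges), strict=False)
        np.testing.assert_allclose(single_node_lesions(g), 0.0, atol=1e-12)

    def test_isolated_node_positive_delta(self):
        g = DirectedConnectome(5, frozenset({(0, 1), (1, 2), (2, 3)}))
        assert single_node_lesions(g)[4] > 0


class TestTargetedAttack:
    def test_curve_count_is_modules_plus_random(self, four_module_partition):
        g = random_directed_graph(12, 60, seed=8)
        res = targeted_attack(g, four_module_partition, n_reps=2, seed=9)
        assert res.schedule.nunique() == 5  # 4 modules + random

    def test_reproducible_with_seed(self, four_module_partition):
        g = random_directed_graph(12, 60, seed=10)
        a = targeted_attack(g, four_module_partition, n_reps=3, seed=11)
        b = targeted_attack(g, four_module_partition, n_reps=3, seed=11)
        assert a.equals(b)

    def test_curves_have_baseline_and_module_length(self, four_module_partition):
        g = random_directed_graph(12, 60, seed=12)
        res = targeted_attack(g, four_module_partition, n_reps=1, seed=13)
        for name in four_module_partition.module_names:
            sub = res[res.schedule == name]
            assert sub.step.tolist() == list(range(4))  # 3 nodes + baseline
            assert sub["pct_change"].iloc[0] == 0.0

    def test_planted_hub_module_steepest(self):
        # module A nodes wired to everything: deleting them is costly
        labels = tuple(np.repeat(["A", "B", "C"], 5))
        part = NetworkPartition(labels)
        rng = np.random.default_rng(14)
        edges = set()
        for hub in range(5):
            for other in range(5, 15):
                edges.add((hub, other) if rng.random() < 0.5 else (other, hub))
        for _ in range(10):
            i, j = rng.integers(5, 15, 2)
            if i != j and (j, i) not in edges:
                edges.add((int(i), int(j)))
        g = DirectedConnectome(15, frozenset(edges))
        res = targeted_attack(g, part, n_reps=5, seed=15)
        slopes = res.drop_duplicates("schedule").set_index("schedule").mean_slope
        assert slopes.idxmin() == "A"
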