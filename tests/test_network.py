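"""Correlation graphs, proportional thresholding and degree statistics.

The within-/between-network statistics are cross-checked against a
deliberately naive brute-force implementation (explicit pair loops) on
random small instances.
"""

import numpy as np
import pandas as pd
import pytest

from learnconn.network import (
    AdjacencyMatrix,
    CorrelationMatrix,
    between_network_connectivity,
    correlation_matrix,
    link_budget,
    node_degrees,
    proportional_threshold,
    subject_condition_metrics,
    within_network_connectivity,
)
from learnconn.preprocess import Parcellation, RoiTimeSeriesMatrix


def brute_threshold(corr, p):
    """Rank all pairs by signed value; keep top floor(p*M) pairs."""
    n = corr.shape[0]
    pairs = [
        (corr[i, j], i, j) for i in range(n) for j in range(i + 1, n)
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    L = int(np.floor(p * n * (n - 1) / 2))
    adj = np.zeros((n, n), dtype=bool)
    for _, i, j in pairs[:L]:
        adj[i, j] = adj[j, i] = True
    return adj


def brute_within(adj, members):
    degs = [sum(adj[i, j] for j in range(adj.shape[0])) for i in members]
    return sum(degs) / len(degs)


def brute_between(adj, a, b):
    return sum(adj[i, j] for i in a for j in b)


def toy_parc(labels):
    return Parcellation(
        pd.DataFrame(
            {
                "node_id": [f"n{i}" for i in range(len(labels))],
                "x": 0.0, "y": 0.0, "z": 0.0,
                "network": labels,
            }
        )
    )


def toy_adjacency(n, links):
    adj = np.zeros((n, n), dtype=bool)
    for i, j in links:
        adj[i, j] = adj[j, i] = True
    return AdjacencyMatrix(adj, tuple(f"n{i}" for i in range(n)))


class TestCorrelation:
    def test_matches_direct_computation(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((5, 3))
        corr = correlation_matrix(RoiTimeSeriesMatrix(data))
        centered = data - data.mean(axis=0)
        for i in range(3):
            for j in range(3):
                expected = (centered[:, i] @ centered[:, j]) / (
                    np.linalg.norm(centered[:, i]) * np.linalg.norm(centered[:, j])
                )
                assert corr.data[i, j] == pytest.approx(expected)

    def test_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        data = np.stack([x, x, -x], axis=1)
        corr = correlation_matrix(RoiTimeSeriesMatrix(data))
        assert corr.data[0, 1] == pytest.approx(1.0)
        assert corr.data[0, 2] == pytest.approx(-1.0)

    def test_zero_variance_column_named(self):
        data = np.ones((10, 2))
        data[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="n1"):
            correlation_matrix(RoiTimeSeriesMatrix(data))


class TestThreshold:
    def test_full_parcellation_link_budget(self):
        assert link_budget(264, 0.25) == 8679

    def test_toy_ranking(self):
        c = np.eye(4)
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.1,
                (1, 2): 0.05, (1, 3): -0.2, (2, 3): -0.4}
        for (i, j), v in vals.items():
            c[i, j] = c[j, i] = v
        adj = proportional_threshold(
            CorrelationMatrix(c, ("a", "b", "c", "d")), 0.25
        )
        assert adj.link_count == 1
        assert adj.data[0, 1]

    def test_p_one_gives_complete_graph(self):
        rng = np.random.default_rng(2)
        c = np.corrcoef(rng.standard_normal((20, 6)), rowvar=False)
        adj = proportional_threshold(
            CorrelationMatrix(c, tuple("abcdef")), 1.0
        )
        assert adj.link_count == 15

    def test_invalid_p_rejected(self):
        c = CorrelationMatrix(np.eye(3), ("a", "b", "c"))
        for p in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                proportional_threshold(c, p)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            n = 10
            m = rng.uniform(-1, 1, (n, n))
            c = (m + m.T) / 2
            np.fill_diagonal(c, 1.0)
            cm = CorrelationMatrix(c, tuple(f"n{i}" for i in range(n)))
            p = rng.uniform(0.05, 1.0)
            adj = proportional_threshold(cm, p)
            np.testing.assert_array_equal(adj.data, brute_threshold(c, p))

    def test_monotone_in_single_value(self):
        """Raising one correlation never removes that pair's link."""
        rng = np.random.default_rng(4)
        n = 8
        m = rng.uniform(-1, 1, (n, n))
        c = (m + m.T) / 2
        np.fill_diagonal(c, 1.0)
        ids = tuple(f"n{i}" for i in range(n))
        base = proportional_threshold(CorrelationMatrix(c, ids), 0.3)
        for i, j in zip(*np.triu_indices(n, 1)):
            if not base.data[i, j]:
                continue
            c2 = c.copy()
            c2[i, j] = c2[j, i] = min(1.0, c2[i, j] + 0.2)
            raised = proportional_threshold(CorrelationMatrix(c2, ids), 0.3)
            assert raised.data[i, j]

    def test_deterministic_tie_break(self):
        c = np.eye(4)
        c[c == 0] = 0.5  # all off-diagonal values tie
        ids = ("a", "b", "c", "d")
        adj1 = proportional_threshold(CorrelationMatrix(c.copy(), ids), 0.25)
        adj2 = proportional_threshold(CorrelationMatrix(c.copy(), ids), 0.25)
        np.testing.assert_array_equal(adj1.data, adj2.data)
        assert adj1.data[0, 1]  # lexicographically first pair wins


class TestDegreeStatistics:
    def test_degrees_toy(self):
        adj = toy_adjacency(4, [(0, 1), (1, 2), (2, 3)])
        np.testing.assert_array_equal(node_degrees(adj), [1, 2, 2, 1])

    def test_degree_sum_is_twice_links(self):
        rng = np.random.default_rng(5)
        c = np.corrcoef(rng.standard_normal((40, 12)), rowvar=False)
        adj = proportional_threshold(
            CorrelationMatrix(c, tuple(f"n{i}" for i in range(12))), 0.25
        )
        assert node_degrees(adj).sum() == 2 * adj.link_count

    def test_within_toy(self):
        adj = toy_adjacency(4, [(0, 1), (1, 2), (2, 3)])
        parc = toy_parc(["A", "A", "B", "B"])
        assert within_network_connectivity(adj, parc, "A") == pytest.approx(1.5)

    def test_within_complete_and_empty(self):
        n = 6
        parc = toy_parc(["A"] * 3 + ["B"] * 3)
        complete = toy_adjacency(
            n, [(i, j) for i in range(n) for j in range(i + 1, n)]
        )
        empty = toy_adjacency(n, [])
        assert within_network_connectivity(complete, parc, "A") == n - 1
        assert within_network_connectivity(empty, parc, "B") == 0

    def test_between_toy(self):
        adj = toy_adjacency(4, [(0, 1), (1, 2), (2, 3)])
        parc = toy_parc(["A", "A", "B", "B"])
        assert between_network_connectivity(adj, parc, "A", "B") == 1

    def test_between_complete_graph_product(self):
        na, nb = 5, 3
        n = na + nb
        parc = toy_parc(["A"] * na + ["B"] * nb)
        complete = toy_adjacency(
            n, [(i, j) for i in range(n) for j in range(i + 1, n)]
        )
        assert between_network_connectivity(complete, parc, "A", "B") == na * nb

    def test_between_requires_disjoint_labels(self):
        adj = toy_adjacency(3, [])
        parc = toy_parc(["A", "A", "B"])
        with pytest.raises(ValueError):
            between_network_connectivity(adj, parc, "A", "A")

    def test_unknown_label_rejected(self):
        adj = toy_adjacency(3, [])
        parc = toy_parc(["A", "A", "B"])
        with pytest.raises(KeyError):
            within_network_connectivity(adj, parc, "C")

    def test_metrics_match_brute_force(self):
        """Full oracle equivalence on random 10-node graphs."""
        rng = np.random.default_rng(6)
        labels = ["A"] * 4 + ["B"] * 3 + ["other"] * 3
        parc = toy_parc(labels)
        for trial in range(20):
            m = rng.uniform(-1, 1, (10, 10))
            c = (m + m.T) / 2
            np.fill_diagonal(c, 1.0)
            adj = proportional_threshold(
                CorrelationMatrix(c, parc.node_ids), 0.25
            )
            a_idx = [0, 1, 2, 3]
            b_idx = [4, 5, 6]
            assert within_network_connectivity(adj, parc, "A") == pytest.approx(
                brute_within(adj.data, a_idx)
            )
            assert within_network_connectivity(adj, parc, "B") == pytest.approx(
                brute_within(adj.data, b_idx)
            )
            assert between_network_connectivity(adj, parc, "A", "B") == (
                brute_between(adj.data, a_idx, b_idx)
            )


class TestSubjectConditionMetrics:
    def test_equal_links_and_node_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        n = 12
        labels = ["DMN"] * 4 + ["FPN"] * 3 + ["other"] * 5
        parc = toy_parc(labels)
        series = {
            ("s1", "rest"): RoiTimeSeriesMatrix(
                rng.standard_normal((40, n)), node_ids=parc.node_ids
            ),
            ("s1", "EL-learn"): RoiTimeSeriesMatrix(
                rng.standard_normal((40, n)), node_ids=parc.node_ids
            ),
        }
        metrics = subject_condition_metrics(series, parc)
        assert metrics["links"].nunique() == 1

        # permuting node order leaves all metric values unchanged
        perm = rng.permutation(n)
        parc_p = toy_parc([labels[i] for i in perm])
        series_p = {
            key: RoiTimeSeriesMatrix(
                ts.data[:, perm], node_ids=parc_p.node_ids
            )
            for key, ts in series.items()
        }
        metrics_p = subject_condition_metrics(series_p, parc_p)
        for col in ("within_DMN", "within_FPN", "between_DMN_FPN"):
            np.testing.assert_allclose(metrics[col], metrics_p[col])

    def test_node_count_mismatch_rejected(self):
        parc = toy_parc(["DMN", "FPN", "other"])
        series = {("s1", "rest"): RoiTimeSeriesMatrix(np.random.default_rng(8).standard_normal((20, 4)))}
        with pytest.raises(ValueError):
            subject_condition_metrics(series, parc)
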