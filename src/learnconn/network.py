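"""Correlation graphs, proportional thresholding and degree statistics.

A subject's functional network is the binary graph obtained by ranking all
pairwise Pearson correlations between node time series and keeping the top
fraction ``p`` (default 25%) as links.  Because the link budget
``L = floor(p * N(N-1)/2)`` depends only on the node count and ``p``, every
subject's graph has the same number of links and degree-based statistics are
comparable across subjects.

Two statistics summarize a labeled subnetwork:

* within-network connectivity — the mean *full* degree over the member
  nodes, counting links to nodes both inside and outside the subnetwork;
* between-network connectivity — the number of links with one endpoint in
  each of two disjoint subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from learnconn.preprocess import Parcellation, RoiTimeSeriesMatrix

DEFAULT_THRESHOLD_P = 0.25


@dataclass
class CorrelationMatrix:
    """Symmetric node-by-node Pearson correlation matrix."""

    data: np.ndarray
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = self.data.shape[0]
        if self.data.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if len(self.node_ids) != n:
            raise ValueError("node_ids must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]


@dataclass
class AdjacencyMatrix:
    """Binary symmetric graph with a fixed link budget."""

    data: np.ndarray
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        n = self.data.shape[0]
        if self.data.shape != (n, n):
            raise ValueError("adjacency matrix must be square")
        if self.data.diagonal().any():
            raise ValueError("adjacency diagonal must be zero")
        if not (self.data == self.data.T).all():
            raise ValueError("adjacency must be symmetric")
        if len(self.node_ids) != n:
            raise ValueError("node_ids must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def link_count(self) -> int:
        return int(self.data.sum()) // 2


def link_budget(n_nodes: int, p: float) -> int:
    """Number of links kept by proportional thresholding at fraction ``p``."""
    return floor(p * n_nodes * (n_nodes - 1) / 2)


def correlation_matrix(ts: RoiTimeSeriesMatrix) -> CorrelationMatrix:
    """Pairwise Pearson correlations of the node time series."""
    if ts.n_volumes < 3:
        raise ValueError("at least 3 volumes required for correlations")
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.node_ids[j] for j in dead[:5]]
        raise ValueError(f"zero-variance node(s): {names}")
    corr = np.corrcoef(ts.data, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(corr, ts.node_ids)


def proportional_threshold(
    corr: CorrelationMatrix,
    p: float = DEFAULT_THRESHOLD_P,
    ranking: str = "signed",
) -> AdjacencyMatrix:
    """Keep the top fraction ``p`` of correlation values as links.

    ``ranking="signed"`` (default) ranks by signed value, so the most
    positive correlations become links; ``"absolute"`` ranks by magnitude.
    Ties at the cutoff are broken lexicographically by node pair, making the
    result deterministic.
    """
    if not 0 < p <= 1:
        raise ValueError("threshold proportion p must lie in (0, 1]")
    if ranking not in ("signed", "absolute"):
        raise ValueError("ranking must be 'signed' or 'absolute'")
    n = corr.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    values = corr.data[iu, ju]
    key = values if ranking == "signed" else np.abs(values)
    # lexsort: primary descending value, then (i, j) ascending for ties
    order = np.lexsort((ju, iu, -key))
    keep = order[: link_budget(n, p)]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    adj |= adj.T
    return AdjacencyMatrix(adj, corr.node_ids)


def node_degrees(adj: AdjacencyMatrix) -> np.ndarray:
    """Degree of every node (number of links to the rest of the graph)."""
    return adj.data.sum(axis=1).astype(int)


def within_network_connectivity(
    adj: AdjacencyMatrix, parc: Parcellation, label: str
) -> float:
    """Mean full degree over the nodes carrying ``label``.

    Links to nodes outside the subnetwork count too; the statistic reflects
    the total wiring of the subnetwork's members, not just internal links.
    """
    members = parc.members(label)
    return float(node_degrees(adj)[members].mean())


def between_network_connectivity(
    adj: AdjacencyMatrix, parc: Parcellation, label_a: str, label_b: str
) -> int:
    """Number of links with one endpoint in each of two disjoint subnetworks."""
    if label_a == label_b:
        raise ValueError("labels must be distinct")
    a = parc.members(label_a)
    b = parc.members(label_b)
    if np.intersect1d(a, b).size:
        raise ValueError(f"{label_a!r} and {label_b!r} share nodes")
    return int(adj.data[np.ix_(a, b)].sum())


def subject_condition_metrics(
    series: Mapping[tuple[str, str], RoiTimeSeriesMatrix],
    parc: Parcellation,
    p: float = DEFAULT_THRESHOLD_P,
    labels: Iterable[str] = ("DMN", "FPN"),
    between_pairs: Iterable[tuple[str, str]] = (("DMN", "FPN"),),
    ranking: str = "signed",
) -> pd.DataFrame:
    """Connectivity statistics for every (subject, condition) run.

    Returns a tidy frame with one row per run: within-network connectivity
    per label (``within_<label>``), between-network link counts per pair
    (``between_<A>_<B>``), and the common link count as a consistency check.
    """
    labels = tuple(labels)
    between_pairs = tuple(between_pairs)
    rows = []
    for (subject, condition), ts in series.items():
        if ts.n_nodes != len(parc):
            raise ValueError(
                f"run ({subject}, {condition}) has {ts.n_nodes} nodes; "
                f"parcellation has {len(parc)}"
            )
        adj = proportional_threshold(correlation_matrix(ts), p, ranking)
        row: dict[str, object] = {
            "subject": subject,
            "condition": condition,
            "links": adj.link_count,
        }
        for label in labels:
            row[f"within_{label}"] = within_network_connectivity(adj, parc, label)
        for a, b in between_pairs:
            row[f"between_{a}_{b}"] = between_network_connectivity(adj, parc, a, b)
        rows.append(row)
    return pd.DataFrame(rows)
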