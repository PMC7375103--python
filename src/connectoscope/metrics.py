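"""Integration, segregation, and nodal-influence measures for weighted networks.

Path-based measures run on the connection-length matrix ``L = 1/W``:
stronger connections are shorter.  Characteristic path length, global
efficiency and clustering can be computed after normalizing the weight
matrix by its total weight sum (mode ``"total-weight"``, the default),
which makes the three global measures invariant to global rescaling of
the raw weights and hence comparable across subjects; mode ``"none"``
computes them on the stored weights (used by the exact small-graph
oracles).  Degree and strength are always computed on the stored weights.

Weighted clustering is the Onnela geometric-mean-of-triangle-weights
formulation with weights rescaled by their maximum.  Betweenness is the
shortest-path node betweenness on the length matrix, normalized by
(n-1)(n-2) so values lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .build import WeightedNetwork

__all__ = [
    "GlobalMetrics",
    "connection_length_matrix",
    "characteristic_path_length",
    "global_efficiency",
    "clustering_coefficient",
    "nodal_degree",
    "nodal_strength",
    "betweenness_centrality",
    "nodal_metric_table",
    "global_metrics",
]

NORMALIZATION_MODES = ("total-weight", "none")


@dataclass(frozen=True)
class GlobalMetrics:
    """Network-level summary: integration and segregation measures."""

    char_path_length: float
    global_efficiency: float
    clustering_coefficient: float
    n_disconnected_pairs: int
    normalization: str

    def to_dict(self) -> dict:
        return {
            "char_path_length": self.char_path_length,
            "global_efficiency": self.global_efficiency,
            "clustering_coefficient": self.clustering_coefficient,
            "n_disconnected_pairs": self.n_disconnected_pairs,
            "normalization": self.normalization,
        }


def _mode_weights(net: WeightedNetwork, normalization: str) -> np.ndarray:
    if normalization not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {normalization!r}")
    w = net.weights
    if normalization == "total-weight":
        total = w.sum() / 2.0  # sum over undirected edges
        if total == 0:
            raise ValueError("network has no edges; cannot total-weight normalize")
        w = w / total
    return w


def connection_length_matrix(net: WeightedNetwork, normalization: str = "total-weight") -> np.ndarray:
    """Map weights to lengths: ``L_ij = 1/w_ij``, absent edges infinite, diagonal 0."""
    w = _mode_weights(net, normalization)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def _shortest_path_matrix(net: WeightedNetwork, normalization: str) -> np.ndarray:
    lengths = connection_length_matrix(net, normalization)
    finite = np.where(np.isfinite(lengths), lengths, 0.0)
    d = shortest_path(csr_matrix(finite), method="D", directed=False)
    return d


def characteristic_path_length(net: WeightedNetwork, normalization: str = "total-weight") -> tuple[float, int]:
    """Mean shortest-path length over connected ordered node pairs.

    Returns ``(mean_length, n_disconnected_pairs)``; disconnected ordered
    pairs are excluded from the mean and counted.
    """
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not np.any(net.weights > 0):
        raise ValueError("network has no edges; path length undefined")
    d = _shortest_path_matrix(net, normalization)
    off = ~np.eye(net.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    n_disconnected = int(np.count_nonzero(off) - np.count_nonzero(finite))
    return float(d[finite].mean()), n_disconnected


def global_efficiency(net: WeightedNetwork, normalization: str = "total-weight") -> float:
    """Mean inverse shortest-path length over ordered node pairs (1/inf = 0)."""
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not np.any(net.weights > 0):
        return 0.0
    d = _shortest_path_matrix(net, normalization)
    off = ~np.eye(net.n_nodes, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(d[off] > 0, 1.0 / d[off], 0.0)
    inv[~np.isfinite(d[off])] = 0.0
    return float(inv.mean())


def clustering_coefficient(
    net: WeightedNetwork, normalization: str = "total-weight"
) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering per node, plus the network mean.

    ``C_i = (1/(k_i (k_i - 1))) * sum_{jk} (ŵ_ij ŵ_ik ŵ_jk)^{1/3}`` with
    weights ŵ rescaled by the maximum weight; nodes with degree < 2 get 0.
    The total-weight mode rescales first, but the subsequent max-rescale
    makes C invariant to it -- both modes are accepted for symmetry with
    the path measures.
    """
    w = _mode_weights(net, normalization)
    G = nx.from_numpy_array(w)
    cc = nx.clustering(G, weight="weight")
    values = np.array([cc[i] for i in range(net.n_nodes)])
    return values, float(values.mean())


def nodal_degree(net: WeightedNetwork) -> np.ndarray:
    """Number of nonzero edges incident to each node."""
    return np.count_nonzero(net.weights > 0, axis=1)


def nodal_strength(net: WeightedNetwork) -> np.ndarray:
    """Sum of incident edge weights per node."""
    return net.weights.sum(axis=1)


def betweenness_centrality(net: WeightedNetwork, normalization: str = "total-weight") -> np.ndarray:
    """Shortest-path node betweenness on the length matrix, in [0, 1].

    Raw pair dependencies (equal-length multiplicity shared fractionally)
    are divided by (n-1)(n-2).  Invariant to the weight normalization mode
    because shortest paths are rank-preserved under global rescale.
    """
    n = net.n_nodes
    if n < 3:
        raise ValueError("betweenness requires at least 3 nodes")
    lengths = connection_length_matrix(net, normalization)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    finite = np.isfinite(lengths[iu, ju])
    G.add_weighted_edges_from(
        zip(iu[finite].tolist(), ju[finite].tolist(), lengths[iu, ju][finite].tolist()),
        weight="length",
    )
    raw = nx.betweenness_centrality(G, weight="length", normalized=False)
    return np.array([raw[i] for i in range(n)]) / ((n - 1) * (n - 2))


def nodal_metric_table(
    net: WeightedNetwork, normalization: str = "total-weight"
) -> pd.DataFrame:
    """Per-node degree, strength, and betweenness for one network."""
    return pd.DataFrame(
        {
            "label": net.atlas.region_labels,
            "degree": nodal_degree(net),
            "strength": nodal_strength(net),
            "betweenness": betweenness_centrality(net, normalization),
        }
    )


def global_metrics(net: WeightedNetwork, normalization: str = "total-weight") -> GlobalMetrics:
    """Characteristic path length, global efficiency, and mean clustering."""
    cpl, n_disc = characteristic_path_length(net, normalization)
    eff = global_efficiency(net, normalization)
    _, mean_cc = clustering_coefficient(net, normalization)
    return GlobalMetrics(cpl, eff, mean_cc, n_disc, normalization)
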