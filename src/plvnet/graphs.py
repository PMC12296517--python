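"""Weighted electrode-level graphs and their efficiency/clustering summaries.

Nodes are the 31 ROI electrodes; edge weights are windowed rPLV values with
negative values clipped to zero (absent edge), since shortest-path lengths
require nonnegative weights.  Global efficiency is the mean inverse
shortest-path length over ordered node pairs,

    E_glob = 1 / (N (N-1)) * sum_{i != j} 1 / L_ij,

with disconnected pairs contributing zero.  In ``binary`` mode L_ij is the
hop count on the positive-weight skeleton (the convention of the networkx
``global_efficiency`` call); in ``weighted`` mode L_ij is the Dijkstra
length under edge distances 1/w.  Average clustering is the mean nodal
clustering coefficient — triangle fraction in binary mode, the
geometric-mean intensity variant (weights rescaled by the maximum) in
weighted mode.  Degree-<2 nodes contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .config import DEFAULT_ROI_MAP, RoiMap, window_mask
from .connectivity import Connectivity

__all__ = [
    "GraphSummary",
    "graph_from_window",
    "global_efficiency",
    "average_clustering",
    "summarize_graph",
]


@dataclass
class GraphSummary:
    """Per subject x window graph metrics."""

    subject_id: str
    window: tuple[float, float]
    e_glob: float
    clustering: float
    mode: str


def graph_from_window(
    conn: Connectivity,
    roi: RoiMap = DEFAULT_ROI_MAP,
    window: tuple[float, float] = (0.0, 500.0),
) -> nx.Graph:
    """Build the undirected weighted graph of windowed rPLV over ROI electrodes.

    Edge weight = time-averaged rPLV over the window, clipped below at 0;
    zero-weight edges are omitted.  Every ROI electrode is a node even if
    isolated.
    """
    mask = window_mask(conn.times, window)
    w = conn.rplv[:, mask].mean(axis=1)
    if np.isnan(w).any():
        raise ValueError("unusable pairs present; graph undefined")
    labels = conn.channel_labels
    nodes = list(roi.electrodes)
    node_set = set(labels.index(lab) for lab in nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (i, j), weight in zip(conn.pairs, w):
        if i in node_set and j in node_set and weight > 0:
            g.add_edge(labels[i], labels[j], weight=float(weight),
                       distance=1.0 / float(weight))
    return g


def global_efficiency(graph: nx.Graph, mode: str = "binary") -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("global efficiency needs >= 2 nodes")
    if mode == "binary":
        return float(nx.global_efficiency(graph))
    if mode != "weighted":
        raise ValueError("mode must be 'binary' or 'weighted'")
    for _, _, d in graph.edges(data=True):
        if "distance" not in d:
            d["distance"] = 1.0 / d["weight"]
    total = 0.0
    for _, lengths in nx.all_pairs_dijkstra_path_length(graph, weight="distance"):
        for v, L in lengths.items():
            if L > 0:
                total += 1.0 / L
    return total / (n * (n - 1))


def average_clustering(graph: nx.Graph, mode: str = "binary") -> float:
    """Mean nodal clustering coefficient (binary triangles or weight intensity)."""
    if graph.number_of_nodes() < 1:
        raise ValueError("average clustering needs >= 1 node")
    if mode == "binary":
        return float(nx.average_clustering(graph))
    if mode != "weighted":
        raise ValueError("mode must be 'binary' or 'weighted'")
    return float(nx.average_clustering(graph, weight="weight"))


def summarize_graph(
    conn: Connectivity,
    roi: RoiMap = DEFAULT_ROI_MAP,
    window: tuple[float, float] = (0.0, 500.0),
    mode: str = "binary",
    subject_id: str = "",
) -> GraphSummary:
    """Windowed graph metrics for one subject."""
    g = graph_from_window(conn, roi, window)
    return GraphSummary(
        subject_id=subject_id,
        window=tuple(window),
        e_glob=global_efficiency(g, mode),
        clustering=average_clustering(g, mode),
        mode=mode,
    )
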