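"""Tree-map style cluster visualization: exact k-nearest-neighbour graph
over latent features, minimum spanning tree, GraphML export.

At desk scale the approximations of large-scale tree-map layouts are
unnecessary, so both the kNN graph and the MST are exact; rendering is
delegated to standard graph tooling via GraphML (plus an optional static
force-layout PNG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
from sklearn.neighbors import NearestNeighbors

from .extractors import LatentFeatures


@dataclass
class NeighborGraph:
    edges: list          # (i, j, weight) with i < j, undirected, unique
    n_nodes: int
    k: int


@dataclass
class TreeLayout:
    mst_edges: list      # (i, j, weight)
    node_labels: Optional[np.ndarray] = None
    node_coords: Optional[np.ndarray] = None
    n_nodes: int = 0
    n_components: int = 1


def knn_graph(Z, k: int) -> NeighborGraph:
    """Exact Euclidean k-nearest-neighbour graph, folded undirected.

    Distance ties are broken by the lower point index.
    """
    Zm = Z.matrix if isinstance(Z, LatentFeatures) else np.asarray(Z, dtype=float)
    n = len(Zm)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Zm)
    dist, nbrs = nn.kneighbors(Zm)
    edges = {}
    for i in range(n):
        taken = 0
        for d, j in zip(dist[i], nbrs[i]):
            j = int(j)
            if j == i:
                continue
            key = (min(i, j), max(i, j))
            if key not in edges:
                edges[key] = float(d)
            taken += 1
            if taken == k:
                break
    edge_list = sorted((i, j, w) for (i, j), w in edges.items())
    return NeighborGraph(edges=edge_list, n_nodes=n, k=k)


def _to_nx(graph: NeighborGraph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(graph.n_nodes))
    for i, j, w in graph.edges:
        G.add_edge(i, j, weight=w)
    return G


def mst(graph: NeighborGraph) -> TreeLayout:
    """Minimum spanning forest (Kruskal, lexicographic tie-break)."""
    G = _to_nx(graph)
    # stable tie-break: sort by (weight, i, j) and run union-find ourselves
    parent = list(range(graph.n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = sorted(graph.edges, key=lambda e: (e[2], e[0], e[1]))
    mst_edges = []
    for i, j, w in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            mst_edges.append((i, j, w))
    n_components = graph.n_nodes - len(mst_edges)
    return TreeLayout(mst_edges=mst_edges, n_nodes=graph.n_nodes,
                      n_components=n_components)


def export_graph(layout: TreeLayout, true_labels, cluster_labels, path,
                 label_names=None) -> None:
    """Write the tree as GraphML with both label sets as node attributes."""
    if layout.n_nodes == 0:
        raise ValueError("empty layout")
    t = np.asarray(true_labels, dtype=int)
    c = np.asarray(cluster_labels, dtype=int)
    if len(t) != layout.n_nodes or len(c) != layout.n_nodes:
        raise ValueError("label vectors must match the number of nodes")
    G = nx.Graph()
    for i in range(layout.n_nodes):
        attrs = dict(true_label=int(t[i]), cluster_label=int(c[i]))
        if label_names is not None and t[i] < len(label_names):
            attrs["true_name"] = str(label_names[t[i]])
        if layout.node_coords is not None:
            attrs["x"] = float(layout.node_coords[i, 0])
            attrs["y"] = float(layout.node_coords[i, 1])
        G.add_node(i, **attrs)
    for i, j, w in layout.mst_edges:
        G.add_edge(i, j, weight=float(w))
    nx.write_graphml(G, path)


def transition_adjacency_fraction(layout: TreeLayout, labels,
                                  transition_label: int,
                                  flank_lookup=None) -> float:
    """Fraction of transition-labeled nodes with at least one MST
    neighbour carrying a (different) activity label — the tree-level
    signature of transitions bridging their flanking activities."""
    labels = np.asarray(labels, dtype=int)
    adj = {i: set() for i in range(layout.n_nodes)}
    for i, j, _ in layout.mst_edges:
        adj[i].add(j)
        adj[j].add(i)
    trans_nodes = np.flatnonzero(labels == transition_label)
    if len(trans_nodes) == 0:
        raise ValueError("no transition-labeled nodes")
    hits = 0
    for i in trans_nodes:
        neigh_labels = {int(labels[j]) for j in adj[i]}
        if flank_lookup is not None:
            if neigh_labels & set(flank_lookup.get(int(i), [])):
                hits += 1
        elif any(l != transition_label for l in neigh_labels):
            hits += 1
    return hits / len(trans_nodes)


def plot_tree(layout: TreeLayout, labels, path, seed: int = 0) -> None:
    """Optional static 2-D force-layout plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    G = nx.Graph()
    G.add_nodes_from(range(layout.n_nodes))
    G.add_weighted_edges_from(layout.mst_edges)
    pos = nx.spring_layout(G, seed=seed)
    labels = np.asarray(labels, dtype=int)
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx_edges(G, pos, ax=ax, alpha=0.4)
    xs = np.array([pos[i] for i in range(layout.n_nodes)])
    sc = ax.scatter(xs[:, 0], xs[:, 1], c=labels, cmap="tab10", s=18)
    fig.colorbar(sc, ax=ax, label="label")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
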