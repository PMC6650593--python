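"""Topology panel for undirected networks and Erdős–Rényi baselines.

Covers the standard descriptive statistics of microbial co-occurrence
networks (clustering coefficient, characteristic path length, diameter,
density, degree heterogeneity, Freeman degree centralization, modularity)
together with size-matched G(n, m) random baselines and the small-world
coefficient SW = (C/C_R)/(L/L_R).  Edge signs are ignored for topology; the
fraction of positive edges is reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "TopologySummary",
    "ERBaseline",
    "clustering_coefficient",
    "characteristic_path_length",
    "density_and_neighbors",
    "heterogeneity_and_centralization",
    "er_baseline",
    "small_world",
    "summarize_topology",
]


def _simple_graph(network) -> nx.Graph:
    g = network if isinstance(network, nx.Graph) else network.graph
    if nx.number_of_selfloops(g):
        raise ValueError("graph must be simple (no self-loops)")
    return g


def clustering_coefficient(network) -> float:
    """Mean local clustering coefficient; nodes of degree < 2 contribute 0."""
    g = _simple_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return nx.average_clustering(g, count_zeros=True)


def characteristic_path_length(network) -> tuple[float, int, bool]:
    """(L, diameter, disconnected_flag) over connected node pairs only."""
    g = _simple_graph(network)
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    total = 0.0
    count = 0
    diameter = 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, d in lengths.items():
            if target == source:
                continue
            total += d
            count += 1
            diameter = max(diameter, d)
    disconnected = not nx.is_connected(g)
    return total / count, diameter, disconnected


def density_and_neighbors(network) -> tuple[float, float]:
    """(density 2E/(N(N-1)), average neighbor count 2E/N)."""
    g = _simple_graph(network)
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return 2.0 * e / (n * (n - 1)), 2.0 * e / n


def heterogeneity_and_centralization(network) -> tuple[float, float]:
    """Degree coefficient of variation and Freeman degree centralization."""
    g = _simple_graph(network)
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("need at least 3 nodes")
    k = np.array([d for _, d in g.degree()], dtype=float)
    mean = k.mean()
    heterogeneity = float(np.sqrt(np.mean((k - mean) ** 2)) / mean) if mean > 0 else 0.0
    centralization = float((k.max() - k).sum() / ((n - 1.0) * (n - 2.0)))
    return heterogeneity, centralization


@dataclass
class ERBaseline:
    """Ensemble means (and Monte-Carlo SEs) over G(n, m) replicates."""

    C_R: float
    L_R: float
    modularity_R: float
    heterogeneity_R: float
    centralization_R: float
    C_R_se: float
    L_R_se: float
    reps: int
    seed: int


def er_baseline(
    n_nodes: int, n_edges: int, reps: int = 100, seed: int = 0
) -> ERBaseline:
    """Average topology of uniform G(n, m) graphs with exactly the given size."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges infeasible for {n_nodes} nodes")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    from .modules import louvain_partition  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    cs, ls, qs, hs, zs = [], [], [], [], []
    for _ in range(reps):
        rep_seed = int(rng.integers(2**31 - 1))
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=rep_seed)
        cs.append(clustering_coefficient(g))
        L, _, _ = characteristic_path_length(g)
        ls.append(L)
        qs.append(louvain_partition(g, seed=rep_seed).q)
        h, z = heterogeneity_and_centralization(g)
        hs.append(h)
        zs.append(z)
    def se(v):
        return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
    return ERBaseline(
        float(np.mean(cs)), float(np.mean(ls)), float(np.mean(qs)),
        float(np.mean(hs)), float(np.mean(zs)), se(cs), se(ls), reps, seed,
    )


def small_world(C: float, C_R: float, L: float, L_R: float) -> tuple[float, float, float]:
    """(C/C_R, L/L_R, SW); SW > 1 indicates small-world structure."""
    for name, v in (("C", C), ("C_R", C_R), ("L", L), ("L_R", L_R)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    c_ratio = C / C_R
    l_ratio = L / L_R
    return c_ratio, l_ratio, c_ratio / l_ratio


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    diameter: int
    pos_fraction: float
    avg_neighbors: float
    density: float
    heterogeneity: float
    centralization: float
    modularity: float
    C: float
    L: float
    C_R: float
    L_R: float
    modularity_R: float
    heterogeneity_R: float
    centralization_R: float
    C_ratio: float
    L_ratio: float
    SW: float
    disconnected: bool
    random_reps: int
    seed: int


def summarize_topology(network, random_reps: int = 100, seed: int = 0) -> TopologySummary:
    """Full descriptive panel plus ER baseline and small-world coefficient."""
    from .modules import louvain_partition

    g = _simple_graph(network)
    n, e = g.number_of_nodes(), g.number_of_edges()
    signs = [attrs.get("sign", "+") for _, _, attrs in g.edges(data=True)]
    pos_fraction = (sum(s == "+" for s in signs) / e) if e else float("nan")
    C = clustering_coefficient(g)
    L, diameter, disconnected = characteristic_path_length(g)
    density, avg_neighbors = density_and_neighbors(g)
    heterogeneity, centralization = heterogeneity_and_centralization(g)
    q = louvain_partition(g, seed=seed).q
    base = er_baseline(n, e, reps=random_reps, seed=seed)
    c_ratio, l_ratio, sw = small_world(C, base.C_R, L, base.L_R)
    return TopologySummary(
        n_nodes=n, n_edges=e, diameter=diameter, pos_fraction=pos_fraction,
        avg_neighbors=avg_neighbors, density=density,
        heterogeneity=heterogeneity, centralization=centralization,
        modularity=q, C=C, L=L, C_R=base.C_R, L_R=base.L_R,
        modularity_R=base.modularity_R, heterogeneity_R=base.heterogeneity_R,
        centralization_R=base.centralization_R,
        C_ratio=c_ratio, L_ratio=l_ratio, SW=sw,
        disconnected=disconnected, random_reps=random_reps, seed=seed,
    )
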