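"""Per-(site, depth) association networks and the recurrence-based consensus.

Each series set yields one signed association network (edges pass the
significance screen and the alignment-duration screen).  Networks from the
replicated series sets are then merged: an edge enters the consensus
network only when the same pair co-varies with the same sign in at least
``min_recurrence`` of the input networks.  Recurrence filtering is the
point of the method — associations that appear in a single network are
treated as likely spurious.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .datamodel import ValidationError
from .lsa import Association

__all__ = [
    "AssociationNetwork",
    "ConsensusNetwork",
    "build_network",
    "build_consensus",
    "recurrence_histogram",
    "extract_subnetwork",
    "export_network",
    "read_graphml",
]


@dataclass
class AssociationNetwork:
    """Signed association graph of one (site, depth) series set."""

    network_id: tuple
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ConsensusNetwork:
    """Merged graph whose edges carry recurrence counts and a consensus delay."""

    graph: nx.Graph
    min_recurrence: int
    n_input_networks: int
    member_ids: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    assocs: list[Association],
    alpha: float = 0.001,
    min_span: int = 6,
    network_id: tuple = ("", 0.0),
    node_classes: dict | None = None,
    span_comparator: str = ">",
) -> AssociationNetwork:
    """Screen associations into a signed graph.

    An edge is kept when ``p < alpha`` (strict) and the LSA alignment lasted
    more than ``min_span`` months (strict by default; set
    ``span_comparator=">="`` for an inclusive duration rule).  Nodes are the
    features incident to at least one kept edge.
    """
    if span_comparator not in (">", ">="):
        raise ValueError("span_comparator must be '>' or '>='")
    g = nx.Graph()
    for a in assocs:
        if a.p_value is None or not a.p_value < alpha:
            continue
        long_enough = (
            a.align_length > min_span
            if span_comparator == ">"
            else a.align_length >= min_span
        )
        if not long_enough:
            continue
        g.add_edge(
            a.feature_a, a.feature_b,
            sign=a.sign, delay=int(a.delay), ls=float(a.ls), p=float(a.p_value),
        )
    if node_classes:
        for n in g.nodes:
            g.nodes[n]["feature_class"] = node_classes.get(n, "unknown")
    if g.number_of_edges() == 0:
        warnings.warn(f"network {network_id}: no edges passed the screens")
    return AssociationNetwork(network_id, g)


def build_consensus(
    networks: list[AssociationNetwork], min_recurrence: int = 3
) -> ConsensusNetwork:
    """Merge replicate networks, keeping (pair, sign) edges recurring >= min_recurrence times.

    Recurrence is counted per signed pair: a positive and a negative
    association between the same features are distinct edges and never pool
    their counts.  The consensus delay is the most frequent member delay
    (ties -> smaller |delay|, then positive).
    """
    ids = [n.network_id for n in networks]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate network ids: {ids}")
    if len(networks) < min_recurrence:
        raise ValidationError("fewer input networks than min_recurrence")

    tally: dict[tuple, list] = {}
    for net in networks:
        for u, v, attrs in net.graph.edges(data=True):
            key = (min(u, v), max(u, v), attrs["sign"])
            tally.setdefault(key, []).append((net.network_id, attrs.get("delay", 0)))

    g = nx.Graph()
    chosen: dict[tuple, tuple] = {}
    for (u, v, sign), members in tally.items():
        if len(members) < min_recurrence:
            continue
        delays = Counter(d for _, d in members)
        top = max(delays.values())
        consensus_delay = min(
            (d for d, c in delays.items() if c == top),
            key=lambda d: (abs(d), d < 0),
        )
        prev = chosen.get((u, v))
        if prev is not None:
            # both signs independently recurrent: keep the better-supported
            # sign (ties -> positive); a simple graph holds one edge per pair
            if (len(members), sign == "+") <= (prev[0], prev[1] == "+"):
                continue
            warnings.warn(f"pair ({u}, {v}): both signs recurrent; keeping one")
        chosen[(u, v)] = (len(members), sign)
        g.add_edge(
            u, v,
            sign=sign,
            recurrence=len(members),
            consensus_delay=int(consensus_delay),
            member_networks="|".join(str(m) for m, _ in members),
        )
    node_classes = {}
    for net in networks:
        for n, attrs in net.graph.nodes(data=True):
            if "feature_class" in attrs:
                node_classes[n] = attrs["feature_class"]
    for n in g.nodes:
        if n in node_classes:
            g.nodes[n]["feature_class"] = node_classes[n]
    return ConsensusNetwork(g, min_recurrence, len(networks), ids)


def recurrence_histogram(consensus: ConsensusNetwork, m: int | None = None) -> dict[int, float]:
    """Fraction of consensus edges at each recurrence level (sums to 1)."""
    m = m if m is not None else consensus.n_input_networks
    counts = Counter(
        attrs["recurrence"] for _, _, attrs in consensus.graph.edges(data=True)
    )
    total = sum(counts.values())
    if total == 0:
        return {}
    return {
        r: counts.get(r, 0) / total for r in range(consensus.min_recurrence, m + 1)
    }


def extract_subnetwork(
    consensus: ConsensusNetwork, seed_nodes: list[str]
) -> ConsensusNetwork:
    """Induced subgraph on the seed nodes and their first neighbors."""
    if not seed_nodes:
        raise ValueError("empty seed set")
    present = [s for s in seed_nodes if s in consensus.graph]
    missing = [s for s in seed_nodes if s not in consensus.graph]
    if missing:
        warnings.warn(f"seed node(s) not in network: {missing}")
    if not present:
        raise ValueError("none of the seed nodes are in the network")
    keep = set(present)
    for s in present:
        keep.update(consensus.graph.neighbors(s))
    sub = consensus.graph.subgraph(keep).copy()
    return ConsensusNetwork(
        sub, consensus.min_recurrence, consensus.n_input_networks, consensus.member_ids
    )


def _as_graph(network) -> nx.Graph:
    if isinstance(network, (AssociationNetwork, ConsensusNetwork)):
        return network.graph
    return network


def export_network(network, path, format: str = "graphml") -> None:
    """Write a network as GraphML (attribute-preserving), TSV edge list, or SIF."""
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty network")
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edge_list_tsv":
        rows = [
            {"feature_a": u, "feature_b": v, **attrs}
            for u, v, attrs in g.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, attrs in g.edges(data=True):
                interaction = "pos" if attrs.get("sign", "+") == "+" else "neg"
                fh.write(f"{u}\t{interaction}\t{v}\n")
            for n in nx.isolates(g):
                fh.write(f"{n}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_graphml(path) -> nx.Graph:
    """Round-trip reader for :func:`export_network`'s GraphML output."""
    return nx.read_graphml(path)
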