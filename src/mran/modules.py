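"""Module detection, node roles, module temporal profiles and bloom labeling.

Modules are found with the Louvain algorithm (unweighted by default,
ignoring edge sign).  Node roles follow the classic within-module degree
z-score (Zi) / participation coefficient (Pi) scheme with thresholds
Zi = 2.5 and Pi = 0.62: peripherals, module hubs, connectors and network
hubs.  Module "monthly patterns" average the min-max scaled relative
abundances of non-cyanobacterial member OTUs per month.  Bloom periods are
labeled from the bloom rule: target OTU share above 10% of the whole
community with chl-a above 15 µg/L, or an 80% dominance override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import (
    CYANOBACTERIAL,
    ENVIRONMENTAL,
    NON_CYANOBACTERIAL,
    AbundanceTable,
    SampleKey,
    ValidationError,
)

__all__ = [
    "ModulePartition",
    "NodeRole",
    "BloomCall",
    "louvain_partition",
    "compute_roles",
    "role_census",
    "module_monthly_pattern",
    "label_blooms",
]

PERIPHERAL = "peripheral"
MODULE_HUB = "module hub"
CONNECTOR = "connector"
NETWORK_HUB = "network hub"

Z_THRESHOLD = 2.5
P_THRESHOLD = 0.62


@dataclass
class ModulePartition:
    """Node -> module labels with the partition's modularity Q."""

    labels: dict[str, int]
    q: float
    major_coverage: float = 0.85

    @property
    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.labels.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    @property
    def n_modules(self) -> int:
        return len(set(self.labels.values()))

    @property
    def major_modules(self) -> list[int]:
        """Largest modules whose cumulative node coverage reaches the threshold."""
        sizes = sorted(self.module_sizes.items(), key=lambda kv: (-kv[1], kv[0]))
        total = sum(s for _, s in sizes)
        out, cum = [], 0
        for label, size in sizes:
            out.append(label)
            cum += size
            if cum / total >= self.major_coverage:
                break
        return out

    def members(self, label: int) -> list[str]:
        return [n for n, m in self.labels.items() if m == label]


@dataclass
class NodeRole:
    node: str
    zi: float
    pi: float
    category: str


@dataclass
class BloomCall:
    sample: SampleKey
    target_otu: str
    is_bloom: bool
    rule_fired: str  # "proportion+chl", "dominance_override", or "none"


def louvain_partition(
    network, resolution: float = 1.0, seed: int = 0, weighted: bool = False
) -> ModulePartition:
    """Louvain community detection; deterministic for a fixed seed.

    Runs unweighted on the unsigned graph by default; ``weighted=True`` uses
    the LS score stored on the edges (attribute ``ls``) as edge weight.
    """
    g = network if isinstance(network, nx.Graph) else network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    weight = "ls" if weighted else None
    comms = nx.community.louvain_communities(
        g, weight=weight, resolution=resolution, seed=seed
    )
    q = nx.community.modularity(g, comms, weight=weight, resolution=resolution)
    labels = {}
    # stable labels: order modules by size, then smallest member name
    ordered = sorted(comms, key=lambda c: (-len(c), min(str(n) for n in c)))
    for i, comm in enumerate(ordered):
        for n in comm:
            labels[n] = i
    return ModulePartition(labels, float(q))


def compute_roles(network, partition: ModulePartition) -> list[NodeRole]:
    """Zi–Pi role classification of every connected node under a partition.

    Zi is the z-score of a node's within-module degree relative to its
    module (population SD; Zi = 0 when the SD is 0).  Pi = 1 - sum over
    modules of the squared fraction of the node's links into that module.
    """
    g = network if isinstance(network, nx.Graph) else network.graph
    missing = [n for n in g.nodes if n not in partition.labels]
    if missing:
        raise ValidationError(f"partition does not cover node(s): {missing[:5]}")

    within = {}  # node -> degree inside own module
    per_module_links: dict[str, dict[int, int]] = {}
    for n in g.nodes:
        counts: dict[int, int] = {}
        for nb in g.neighbors(n):
            m = partition.labels[nb]
            counts[m] = counts.get(m, 0) + 1
        per_module_links[n] = counts
        within[n] = counts.get(partition.labels[n], 0)

    # module-wise mean/SD of within-degree
    stats: dict[int, tuple[float, float]] = {}
    for label in set(partition.labels.values()):
        members = [n for n in g.nodes if partition.labels[n] == label]
        if not members:
            continue
        vals = np.array([within[n] for n in members], dtype=float)
        stats[label] = (float(vals.mean()), float(vals.std()))  # population SD

    roles = []
    for n in g.nodes:
        k = g.degree(n)
        if k == 0:
            warnings.warn(f"node {n} has no links; Pi undefined, excluded")
            continue
        mean, sd = stats[partition.labels[n]]
        zi = (within[n] - mean) / sd if sd > 0 else 0.0
        pi = 1.0 - sum((c / k) ** 2 for c in per_module_links[n].values())
        if zi > Z_THRESHOLD:
            category = NETWORK_HUB if pi > P_THRESHOLD else MODULE_HUB
        else:
            category = CONNECTOR if pi > P_THRESHOLD else PERIPHERAL
        roles.append(NodeRole(n, float(zi), float(pi), category))
    return roles


def role_census(roles: list[NodeRole]) -> dict[str, float]:
    """Fraction of nodes per role category, plus the Pi = 0 fraction."""
    n = len(roles)
    if n == 0:
        return {c: 0.0 for c in (PERIPHERAL, MODULE_HUB, CONNECTOR, NETWORK_HUB)}
    out = {
        c: sum(r.category == c for r in roles) / n
        for c in (PERIPHERAL, MODULE_HUB, CONNECTOR, NETWORK_HUB)
    }
    out["pi_zero_fraction"] = sum(r.pi == 0.0 for r in roles) / n
    return out


def module_monthly_pattern(
    table: AbundanceTable, partition: ModulePartition, modules: list[int] | None = None
) -> pd.DataFrame:
    """Module x month matrix of mean min-max scaled non-cyanobacterial abundance.

    Each member OTU's series is feature-scaled to [0, 1] across all samples
    ((x - min)/(max - min); constant series map to 0), then averaged over
    member OTUs and over the samples of each year-month.  Cyanobacterial and
    environmental features are excluded.
    """
    months = sorted(set(k.date for k in table.samples))
    labels = modules if modules is not None else sorted(set(partition.labels.values()))
    dates = table.data.index.get_level_values("date")
    rows = {}
    for label in labels:
        members = [
            f for f in partition.members(label)
            if f in table.data.columns
            and table.feature_class[f] == NON_CYANOBACTERIAL
        ]
        if not members:
            warnings.warn(f"module {label} has no non-cyanobacterial members")
            rows[label] = pd.Series(np.nan, index=months)
            continue
        sub = table.data[members]
        rng_ = sub.max() - sub.min()
        scaled = (sub - sub.min()).div(rng_.replace(0.0, np.nan), axis=1).fillna(0.0)
        rows[label] = scaled.groupby(dates).mean().mean(axis=1).reindex(months)
    out = pd.DataFrame(rows).T
    out.index.name = "module"
    return out


def label_blooms(
    table: AbundanceTable,
    target_otus: list[str],
    chl_a: str | pd.Series = "chl_a",
    prop_threshold: float = 0.10,
    chl_threshold: float = 15.0,
    dominance_override: float = 0.80,
) -> list[BloomCall]:
    """Apply the bloom rule to every (sample, target OTU) combination.

    A sample is a bloom for a target OTU when its share of the whole
    community strictly exceeds ``prop_threshold`` while chl-a strictly
    exceeds ``chl_threshold`` µg/L, or — regardless of chl-a — when the
    share strictly exceeds the ``dominance_override``.
    """
    if isinstance(chl_a, str):
        if chl_a not in table.data.columns:
            raise ValidationError(f"chl-a feature {chl_a!r} not in table")
        chl = table.data[chl_a]
    else:
        chl = chl_a
    if (pd.Series(chl).dropna() < 0).any():
        raise ValidationError("negative chl-a concentration")

    calls = []
    for key in table.samples:
        idx = (key.site, key.depth, key.date)
        c = chl.loc[idx] if idx in chl.index else np.nan
        if np.isnan(c):
            warnings.warn(f"sample {key}: chl-a missing, skipped")
            continue
        for otu in target_otus:
            prop = float(table.data.loc[idx, otu])
            if prop > prop_threshold and c > chl_threshold:
                calls.append(BloomCall(key, otu, True, "proportion+chl"))
            elif prop > dominance_override:
                calls.append(BloomCall(key, otu, True, "dominance_override"))
            else:
                calls.append(BloomCall(key, otu, False, "none"))
    return calls
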