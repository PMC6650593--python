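"""End-to-end convenience: series sets -> six networks -> consensus MRAN."""

from __future__ import annotations

from .datamodel import AbundanceTable, split_series
from .lsa import all_pairs_lsa
from .network import AssociationNetwork, ConsensusNetwork, build_consensus, build_network

__all__ = ["infer_networks", "infer_mran"]


def infer_networks(
    table: AbundanceTable,
    D: int = 1,
    n_perm: int = 2000,
    alpha: float = 0.001,
    min_span: int = 6,
    seed: int = 0,
    features: list[str] | None = None,
) -> list[AssociationNetwork]:
    """One screened association network per (site, depth) series set."""
    networks = []
    classes = table.feature_class.to_dict()
    for series in split_series(table):
        assocs = all_pairs_lsa(
            series, D=D, n_perm=n_perm, seed=seed, features=features, alpha=alpha
        )
        networks.append(
            build_network(
                assocs, alpha=alpha, min_span=min_span,
                network_id=series.key, node_classes=classes,
            )
        )
    return networks


def infer_mran(
    table: AbundanceTable,
    D: int = 1,
    n_perm: int = 2000,
    alpha: float = 0.001,
    min_span: int = 6,
    min_recurrence: int = 3,
    seed: int = 0,
    features: list[str] | None = None,
) -> tuple[list[AssociationNetwork], ConsensusNetwork]:
    """Full inference: per-series networks plus their recurrence consensus."""
    networks = infer_networks(
        table, D=D, n_perm=n_perm, alpha=alpha, min_span=min_span,
        seed=seed, features=features,
    )
    return networks, build_consensus(networks, min_recurrence=min_recurrence)
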