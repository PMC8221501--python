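"""Node degrees, cross-network total degree and hub identification.

Degree counts positive and negative edges equally.  The total degree of a
gene is the sum of its degrees across all analysed networks (classically,
the eight Basal-dominant-class networks); hubs are the top-ranked genes by
total degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError
from .network import SignedNetwork


def node_degrees(net: SignedNetwork) -> dict[str, int]:
    """Number of connections of every node (absent genes simply missing)."""
    return dict(net.graph.degree())


@dataclass
class DegreeSummary:
    """Per-network and total degrees plus the total-degree ranking.

    ``per_network`` is genes x networks; ``rank`` orders genes by total
    degree descending, ties broken alphabetically.
    """

    per_network: pd.DataFrame
    total: pd.Series
    rank: list[str]


def total_degree(networks: list[SignedNetwork]) -> DegreeSummary:
    """Sum degrees over networks and rank all genes."""
    if not networks:
        raise ConfigurationError("total_degree needs at least one network")
    names = []
    for idx, net in enumerate(networks):
        names.append(net.name or f"network_{idx}")
    if len(set(names)) != len(names):
        raise ConfigurationError("network names must be unique")
    columns = {
        name: pd.Series(node_degrees(net), dtype=float)
        for name, net in zip(names, networks)
    }
    per_network = pd.DataFrame(columns).fillna(0).astype(int)
    per_network = per_network.sort_index()
    total = per_network.sum(axis=1)
    rank = sorted(total.index, key=lambda g: (-total[g], g))
    return DegreeSummary(per_network=per_network, total=total, rank=rank)


@dataclass
class HubResult:
    """Top-k genes by total degree; ties at the k-th place are included
    rather than truncated, with ``tie_expanded`` flagging that case."""

    genes: list[str]
    tie_expanded: bool = False


def identify_hubs(summary: DegreeSummary, k: int = 2) -> HubResult:
    """The first ``k`` genes of the total-degree ranking.

    If genes beyond position k tie with the k-th gene's total degree, the
    returned list expands to include them all.
    """
    if k < 1:
        raise ConfigurationError("k must be at least 1")
    if k > len(summary.rank):
        raise ConfigurationError(
            f"k={k} exceeds the {len(summary.rank)} ranked genes"
        )
    genes = summary.rank[:k]
    boundary = summary.total[genes[-1]]
    extra = [g for g in summary.rank[k:] if summary.total[g] == boundary]
    return HubResult(genes=genes + extra, tie_expanded=bool(extra))


def write_degree_summary(summary: DegreeSummary, path) -> None:
    """TSV: one row per gene, one column per network, final total column."""
    out = summary.per_network.copy()
    out["total"] = summary.total
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def degree_histogram(summary: DegreeSummary) -> pd.Series:
    """Counts of genes per total-degree value (histogram-ready)."""
    return summary.total.value_counts().sort_index()
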