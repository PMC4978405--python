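"""Hub identification by a rank-combined centrality measure.

Each node receives three centralities on the unweighted graph: degree,
shortest-path betweenness (unnormalized, endpoints excluded) and closeness
(per connected component, (n_c - 1) / sum of within-component distances).
Each centrality is ranked with rank 1 = most central and ties averaged;
the consensus measure is the mean of the three ranks, with final ties
broken deterministically by gene symbol.  The top 5% of nodes (count
rounded half away from zero) are the hubs.
"""

from __future__ import annotations

import math

import networkx as nx
import pandas as pd
from scipy.stats import rankdata

from .containers import Gan


def centralities(gan: Gan, harmonic_closeness: bool = False) -> pd.DataFrame:
    """Per-node centralities, per-measure ranks and the combined rank.

    Rows are ordered ascending by the combined measure (most central
    first), ties broken by gene symbol.  ``harmonic_closeness`` switches
    the closeness definition to the harmonic variant, which handles
    disconnected graphs without the per-component convention.
    """
    graph = gan.to_networkx() if isinstance(gan, Gan) else gan
    if graph.number_of_nodes() < 2:
        raise ValueError("centrality analysis requires at least 2 nodes")
    nodes = sorted(graph.nodes)
    degree = [graph.degree(n) for n in nodes]
    btw = nx.betweenness_centrality(graph, normalized=False, endpoints=False)
    if harmonic_closeness:
        clo = nx.harmonic_centrality(graph)
    else:
        clo = nx.closeness_centrality(graph, wf_improved=False)
    table = pd.DataFrame(
        {
            "gene": nodes,
            "degree": degree,
            "betweenness": [btw[n] for n in nodes],
            "closeness": [clo[n] for n in nodes],
        }
    )
    for measure in ("degree", "betweenness", "closeness"):
        # rank 1 = most central; ties share the average rank
        table[f"rank_{measure}"] = rankdata(-table[measure].to_numpy(), method="average")
    table["combined"] = table[["rank_degree", "rank_betweenness", "rank_closeness"]].mean(axis=1)
    table = table.sort_values(["combined", "gene"], kind="mergesort").reset_index(drop=True)
    return table


def hub_count(n_nodes: int, fraction: float = 0.05) -> int:
    """Number of hubs: fraction of the node count, rounded half away from zero."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"hub fraction must lie in (0, 1], got {fraction}")
    if n_nodes < 1:
        raise ValueError("need at least one node")
    return int(math.floor(fraction * n_nodes + 0.5))


def select_hubs(table: pd.DataFrame, fraction: float = 0.05) -> list[str]:
    """The top-``fraction`` genes by combined centrality rank."""
    k = hub_count(len(table), fraction)
    return table["gene"].head(k).tolist()
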