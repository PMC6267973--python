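"""Signed differential correlation network and key-metabolite ranking.

Nodes are metabolites incident to at least one significant differential
edge; edges carry the sign of r_diff (stronger correlation in females =
positive) and |r_diff| as weight.  Centrality is computed on the unweighted
graph: degree (DC), shortest-path betweenness normalized by (n-1)(n-2)/2
(BC), and closeness (CC) under the Wasserman-Faust component-scaled
convention so values stay comparable in disconnected graphs.  Key
metabolites are the union of the top-k nodes by each metric; top-k degree
nodes are "hubs", top-k betweenness or closeness nodes "bottlenecks".
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "build_network",
    "network_summary",
    "centrality_table",
    "rank_key_nodes",
    "write_graphml",
]

METRIC_COLUMNS = ["metabolite", "degree", "betweenness", "closeness"]


def build_network(edges: pd.DataFrame) -> nx.Graph:
    """Undirected simple graph from a (significance-filtered) edge table."""
    G = nx.Graph()
    if len(edges) == 0:
        warnings.warn("no significant edges: the differential network is empty")
        return G
    for row in edges.itertuples(index=False):
        if row.metabolite_i == row.metabolite_j:
            raise ValueError(f"self-loop on {row.metabolite_i!r}")
        if G.has_edge(row.metabolite_i, row.metabolite_j):
            raise ValueError(
                f"duplicate edge {row.metabolite_i!r} - {row.metabolite_j!r}"
            )
        G.add_edge(
            row.metabolite_i,
            row.metabolite_j,
            r_diff=float(row.r_diff),
            weight=abs(float(row.r_diff)),
            sign=str(row.sign),
        )
    return G


def network_summary(G: nx.Graph) -> dict:
    """Node/edge counts, signed-edge counts, and mean degree 2|E|/|V|."""
    n, e = G.number_of_nodes(), G.number_of_edges()
    signs = [d.get("sign") for _, _, d in G.edges(data=True)]
    return {
        "n_nodes": n,
        "n_edges": e,
        "n_positive": sum(s == "positive" for s in signs),
        "n_negative": sum(s == "negative" for s in signs),
        "mean_degree": (2.0 * e / n) if n else 0.0,
        "empty": n == 0,
    }


def _closeness(G: nx.Graph, convention: str) -> dict:
    if convention == "wf":
        return nx.closeness_centrality(G, wf_improved=True)
    if convention == "raw":
        # 1 / sum of distances to reachable nodes, no normalization.
        out = {}
        for v in G:
            dist = nx.single_source_shortest_path_length(G, v)
            total = sum(dist.values())
            out[v] = 1.0 / total if total > 0 else 0.0
        return out
    raise ValueError(f"unknown closeness convention {convention!r}; use 'wf' or 'raw'")


def centrality_table(G: nx.Graph, closeness_convention: str = "wf") -> pd.DataFrame:
    """Per-node degree, betweenness and closeness centralities."""
    if G.number_of_nodes() == 0:
        return pd.DataFrame(columns=METRIC_COLUMNS)
    deg = dict(G.degree())
    bet = nx.betweenness_centrality(G, normalized=True)
    clo = _closeness(G, closeness_convention)
    nodes = sorted(G.nodes())
    return pd.DataFrame(
        {
            "metabolite": nodes,
            "degree": [deg[v] for v in nodes],
            "betweenness": [bet[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
        }
    )


def _top_k(table: pd.DataFrame, metric: str, k: int) -> set[str]:
    ranked = table.sort_values([metric, "metabolite"], ascending=[False, True])
    return set(ranked["metabolite"].head(k))


def rank_key_nodes(table: pd.DataFrame, top_k: int = 14) -> pd.DataFrame:
    """Flag key metabolites: top-k by degree, betweenness or closeness.

    Adds ``is_hub`` (top-k degree), ``is_bottleneck`` (top-k betweenness or
    closeness) and ``is_key`` (either) and returns the table sorted by
    degree descending, then betweenness descending, then name — the shape
    of a key-node report.  Ties inside a top-k cut are broken by metabolite
    name ascending.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    out = table.copy()
    if len(out) == 0:
        for col in ("is_hub", "is_bottleneck", "is_key"):
            out[col] = pd.Series(dtype=bool)
        return out
    hubs = _top_k(out, "degree", top_k)
    bottlenecks = _top_k(out, "betweenness", top_k) | _top_k(out, "closeness", top_k)
    out["is_hub"] = out["metabolite"].isin(hubs)
    out["is_bottleneck"] = out["metabolite"].isin(bottlenecks)
    out["is_key"] = out["is_hub"] | out["is_bottleneck"]
    out = out.sort_values(
        ["degree", "betweenness", "metabolite"], ascending=[False, False, True]
    )
    out.reset_index(drop=True, inplace=True)
    return out


def write_graphml(G: nx.Graph, path) -> None:
    """GraphML export with sign/weight/r_diff edge attributes (Cytoscape-ready)."""
    nx.write_graphml(G, path, named_key_ids=True)
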