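"""Sub-network extraction, centralities and hub calling.

The sub-network of the selected candidate miRNAs keeps those miRNAs, every
gene adjacent to at least one of them, and the induced edges. Degree,
closeness and betweenness are computed on the full bipartite sub-network
(genes included), but ranking and hub calling are restricted to the
candidate miRNAs: a hub is a miRNA in the top-k (k=10 by default) of all
three centralities simultaneously.

Conventions: closeness is the unnormalized reciprocal of summed shortest
path distances to reachable nodes (a normalized variant is available);
betweenness is the exact unnormalized shortest-path count over unordered
node pairs, endpoints excluded. Ties at the k-th rank boundary are all
included rather than arbitrarily dropped, so a "top-k" set may exceed k.
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd

from .network import BipartiteNetwork, _from_edges

__all__ = ["extract_subnetwork", "centralities", "top_k_overlap",
           "summarize_subnetwork", "to_networkx", "write_centralities",
           "write_graphml"]


def to_networkx(network: BipartiteNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(network.mirna_nodes, partition="mirna")
    g.add_nodes_from(network.gene_nodes, partition="gene")
    g.add_edges_from(network.edges)
    return g


def extract_subnetwork(network: BipartiteNetwork, keep_mirnas) -> BipartiteNetwork:
    """Induced sub-network of the listed miRNAs and their target genes."""
    keep = set(keep_mirnas)
    if not keep:
        raise ValueError("empty miRNA keep set")
    unknown = keep - set(network.mirna_nodes)
    if unknown:
        raise ValueError(f"not miRNA nodes of this network: {sorted(unknown)[:5]}")
    edges = {(m, g) for m, g in network.edges if m in keep}
    genes = {g for _, g in edges}
    return _from_edges(edges, keep, genes)


def centralities(network: BipartiteNetwork, closeness_normalized: bool = False) -> pd.DataFrame:
    """Degree, closeness and betweenness for every node of the network.

    Betweenness is Brandes' exact algorithm (via networkx), undirected,
    unweighted, unnormalized, endpoints excluded. Closeness defaults to
    1 / sum of shortest-path distances to reachable nodes; isolated nodes
    get closeness 0.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    g = to_networkx(network)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    if closeness_normalized:
        closeness = nx.closeness_centrality(g)
    else:
        closeness = {}
        for node in g:
            dist = nx.single_source_shortest_path_length(g, node)
            total = sum(dist.values())  # own distance is 0
            closeness[node] = 1.0 / total if total > 0 else 0.0
    df = pd.DataFrame(
        {
            "node_id": list(network.nodes),
            "partition": network.partition,
            "degree": [g.degree(n) for n in network.nodes],
            "closeness": [closeness[n] for n in network.nodes],
            "betweenness": [betweenness[n] for n in network.nodes],
        }
    )
    for col in ("top_degree", "top_closeness", "top_betweenness", "hub"):
        df[col] = False
    return df


def _top_set(table: pd.DataFrame, column: str, k: int) -> set[str]:
    if k >= len(table):
        return set(table["node_id"])
    ordered = table.sort_values(column, ascending=False, kind="stable")
    boundary = ordered[column].iloc[k - 1]
    return set(ordered.loc[ordered[column] >= boundary, "node_id"])


def top_k_overlap(table: pd.DataFrame, k: int = 10,
                  restrict_to=None) -> tuple[set[str], pd.DataFrame]:
    """Hub set: intersection of the top-k by degree, closeness, betweenness.

    Ranking is restricted to ``restrict_to`` (the candidate miRNAs; genes
    never enter the ranking). Nodes tied with the k-th value are all kept.
    Returns the hub label set and the table with top/hub flags written back.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if restrict_to is None:
        restricted = table[table["partition"] == "mirna"]
    else:
        restricted = table[table["node_id"].isin(set(restrict_to))]
    if restricted.empty:
        raise ValueError("no nodes to rank")
    if k > len(restricted):
        warnings.warn(
            f"k={k} exceeds the {len(restricted)} ranked nodes; "
            "top sets contain every ranked node",
            stacklevel=2,
        )
    tops = {
        "top_degree": _top_set(restricted, "degree", k),
        "top_closeness": _top_set(restricted, "closeness", k),
        "top_betweenness": _top_set(restricted, "betweenness", k),
    }
    hubs = tops["top_degree"] & tops["top_closeness"] & tops["top_betweenness"]
    out = table.copy()
    for col, labels in tops.items():
        out[col] = out["node_id"].isin(labels)
    out["hub"] = out["node_id"].isin(hubs)
    return hubs, out


def summarize_subnetwork(table: pd.DataFrame) -> dict[str, float]:
    """Arithmetic means of the three centralities over all sub-network nodes."""
    if table.empty:
        raise ValueError("empty centrality table")
    return {
        "mean_degree": float(table["degree"].mean()),
        "mean_closeness": float(table["closeness"].mean()),
        "mean_betweenness": float(table["betweenness"].mean()),
    }


def write_centralities(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_graphml(network: BipartiteNetwork, path) -> None:
    nx.write_graphml(to_networkx(network), path)
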