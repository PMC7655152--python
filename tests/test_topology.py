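"""Sub-network extraction, centralities vs brute-force oracle, hub calling."""

import itertools

import networkx as nx
import numpy as np
import pytest

from seedwalk.topology import (
    centralities,
    extract_subnetwork,
    summarize_subnetwork,
    to_networkx,
    top_k_overlap,
)
from .conftest import make_network, random_connected_bipartite


def brute_force_centralities(g: nx.Graph):
    """Independent oracle: BFS distances + exhaustive shortest-path
    enumeration via simple-path listing (feasible for <= 8 nodes)."""
    nodes = list(g)
    closeness, betweenness = {}, {n: 0.0 for n in nodes}
    for n in nodes:
        dist = nx.single_source_shortest_path_length(g, n)
        total = sum(dist.values())
        closeness[n] = 1.0 / total if total > 0 else 0.0
    for s, t in itertools.combinations(nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        d = nx.shortest_path_length(g, s, t)
        shortest = [
            p for p in nx.all_simple_paths(g, s, t, cutoff=d) if len(p) - 1 == d
        ]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(v in p for p in shortest)
            betweenness[v] += through / len(shortest)
    degree = dict(g.degree())
    return degree, closeness, betweenness


class TestExtractSubnetwork:
    def test_induced_subgraph(self):
        net = make_network([("m1", "g1"), ("m2", "g2")])
        sub = extract_subnetwork(net, {"m1"})
        assert sub.nodes == ("m1", "g1")
        assert sub.edges == {("m1", "g1")}

    def test_keep_all_is_identity(self, path4):
        sub = extract_subnetwork(path4, set(path4.mirna_nodes))
        assert sub.edges == path4.edges
        assert sub.nodes == path4.nodes

    def test_shared_gene_kept_once_with_degree_two(self):
        net = make_network([("m1", "g1"), ("m2", "g1"), ("m3", "g9")])
        sub = extract_subnetwork(net, {"m1", "m2"})
        assert sub.gene_nodes == ("g1",)
        assert sub.degrees[sub.node_index["g1"]] == 2

    def test_empty_keep_set_rejected(self, path4):
        with pytest.raises(ValueError, match="empty"):
            extract_subnetwork(path4, set())

    def test_every_gene_in_subnetwork_has_degree(self, rng):
        for _ in range(10):
            net = random_connected_bipartite(rng)
            keep = set(net.mirna_nodes[: max(1, len(net.mirna_nodes) // 2)])
            sub = extract_subnetwork(net, keep)
            gene_deg = sub.degrees[[sub.node_index[g] for g in sub.gene_nodes]]
            assert np.all(gene_deg >= 1)


class TestCentralities:
    def test_path_closeness_and_betweenness(self):
        net = make_network([("m1", "g1"), ("m2", "g1")])  # path m1 - g1 - m2
        table = centralities(net).set_index("node_id")
        assert table.loc["g1", "closeness"] == pytest.approx(0.5)
        assert table.loc["g1", "betweenness"] == pytest.approx(1.0)

    def test_star_center(self, star3):
        table = centralities(star3).set_index("node_id")
        assert table.loc["m1", "degree"] == 3
        assert table.loc["m1", "betweenness"] == pytest.approx(3.0)

    def test_single_edge_no_betweenness(self, single_edge):
        table = centralities(single_edge)
        assert (table["betweenness"] == 0).all()

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(40):
            net = random_connected_bipartite(rng, max_mirna=4, max_gene=4)
            if net.n_nodes > 8:
                continue
            table = centralities(net).set_index("node_id")
            deg, clo, bet = brute_force_centralities(to_networkx(net))
            for n in net.nodes:
                assert table.loc[n, "degree"] == deg[n]
                assert table.loc[n, "closeness"] == pytest.approx(clo[n], abs=1e-12)
                assert table.loc[n, "betweenness"] == pytest.approx(bet[n], abs=1e-9)

    def test_normalized_closeness_variant(self, star3):
        table = centralities(star3, closeness_normalized=True).set_index("node_id")
        assert table.loc["m1", "closeness"] == pytest.approx(1.0)


class TestTopKOverlap:
    def leader_table(self):
        net = make_network(
            [("m1", "g1"), ("m1", "g2"), ("m1", "g3"), ("m2", "g3"), ("m3", "g3")]
        )
        return centralities(net)

    def test_unanimous_leader(self):
        hubs, table = top_k_overlap(self.leader_table(), k=1,
                                    restrict_to={"m1", "m2", "m3"})
        assert hubs == {"m1"}
        assert table.set_index("node_id").loc["m1", "hub"]

    def test_empty_intersection_allowed(self):
        # m1 leads degree; closeness/betweenness led elsewhere on a path
        net = make_network(
            [("m1", "g1"), ("m1", "g2"), ("m1", "g3"), ("m1", "g4"),
             ("m2", "g4"), ("m2", "g5"), ("m3", "g5")]
        )
        table = centralities(net)
        hubs, _ = top_k_overlap(table, k=1, restrict_to={"m1", "m2", "m3"})
        # hub set is the intersection; may be empty when tops disagree
        tops = [
            set(table.sort_values(c, ascending=False)["node_id"][:1])
            for c in ("degree", "closeness", "betweenness")
        ]
        assert hubs <= set.union(*tops)

    def test_boundary_ties_all_included(self):
        net = make_network([("m1", "g1"), ("m2", "g1"), ("m3", "g1"),
                            ("m3", "g2")])
        hubs, table = top_k_overlap(centralities(net), k=2,
                                    restrict_to={"m1", "m2", "m3"})
        # m1 and m2 tie on every centrality; k=2 keeps m3 + both tied nodes
        assert table["top_degree"].sum() >= 3

    @pytest.mark.filterwarnings("ignore:k=.*exceeds")
    def test_hub_subset_of_all_top_sets(self, rng):
        for _ in range(10):
            net = random_connected_bipartite(rng)
            _, table = top_k_overlap(centralities(net), k=3,
                                     restrict_to=set(net.mirna_nodes))
            hub_rows = table[table["hub"]]
            assert hub_rows["top_degree"].all()
            assert hub_rows["top_closeness"].all()
            assert hub_rows["top_betweenness"].all()

    def test_k_exceeding_population_warns(self, single_edge):
        with pytest.warns(UserWarning, match="exceeds"):
            hubs, _ = top_k_overlap(centralities(single_edge), k=10,
                                    restrict_to={"m1"})
        assert hubs == {"m1"}

    def test_bad_k_rejected(self, single_edge):
        with pytest.raises(ValueError):
            top_k_overlap(centralities(single_edge), k=0)


class TestSummary:
    def test_single_edge_mean_degree(self, single_edge):
        assert summarize_subnetwork(centralities(single_edge))["mean_degree"] == 1.0

    def test_path_of_three_mean_degree(self):
        net = make_network([("m1", "g1"), ("m2", "g1")])
        assert summarize_subnetwork(centralities(net))["mean_degree"] == pytest.approx(4 / 3)

    def test_means_within_column_bounds(self, rng):
        net = random_connected_bipartite(rng)
        table = centralities(net)
        s = summarize_subnetwork(table)
        for key, col in [("mean_degree", "degree"),
                         ("mean_closeness", "closeness"),
                         ("mean_betweenness", "betweenness")]:
            assert table[col].min() <= s[key] <= table[col].max()
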