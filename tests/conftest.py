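"""Shared fixtures: tiny hand networks and random bipartite graph samplers."""

from __future__ import annotations

import numpy as np
import pytest

from seedwalk.network import BipartiteNetwork, InteractionTable, _from_edges, build_network


def make_network(pairs) -> BipartiteNetwork:
    """Network from an explicit pair list (miRNA label first)."""
    table = InteractionTable(source_name="test", pairs=frozenset(pairs))
    return build_network(table)


def random_connected_bipartite(
    rng: np.random.Generator,
    max_mirna: int = 8,
    max_gene: int = 8,
    extra_edge_prob: float = 0.2,
) -> BipartiteNetwork:
    """Connected random bipartite graph: a random spanning structure built
    by attaching each new node to the opposite partition, plus extra edges."""
    n_m = int(rng.integers(1, max_mirna + 1))
    n_g = int(rng.integers(1, max_gene + 1))
    mirnas = [f"m{i:03d}" for i in range(n_m)]
    genes = [f"g{j:03d}" for j in range(n_g)]
    edges = {(mirnas[0], genes[0])}
    for i in range(1, n_m):
        edges.add((mirnas[i], genes[int(rng.integers(0, n_g))]))
    for j in range(1, n_g):
        edges.add((mirnas[int(rng.integers(0, n_m))], genes[j]))
    for m in mirnas:
        for g in genes:
            if rng.random() < extra_edge_prob:
                edges.add((m, g))
    return _from_edges(edges, mirnas, genes)


@pytest.fixture
def single_edge():
    return make_network([("m1", "g1")])


@pytest.fixture
def path4():
    """Path m1 - g1 - m2 - g2 (distance strictly increases from m1)."""
    return make_network([("m1", "g1"), ("m2", "g1"), ("m2", "g2")])


@pytest.fixture
def star3():
    """miRNA m1 linked to genes g1, g2, g3."""
    return make_network([("m1", "g1"), ("m1", "g2"), ("m1", "g3")])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
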