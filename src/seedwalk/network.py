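"""Bipartite miRNA-mRNA network construction from interaction tables.

Interaction tables are two-column TSV files (miRNA ID, target gene symbol),
one per source database. Reliable interactions are obtained by intersecting
the per-source tables; the surviving pairs define an undirected bipartite
graph whose column-normalized adjacency matrix is the transition operator of
the random walk.

IDs are treated as opaque, case-sensitive labels: no miRBase nomenclature
normalization is attempted, so upstream tables must already use a consistent
naming scheme.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "TableParseError",
    "InteractionTable",
    "BipartiteNetwork",
    "read_interaction_table",
    "intersect_tables",
    "build_network",
    "load_seed_list",
    "packaged_seed_path",
    "write_network",
    "load_network",
]


class TableParseError(ValueError):
    """A malformed interaction table (wrong field count, empty file...)."""


@dataclass(frozen=True)
class InteractionTable:
    """A deduplicated set of (miRNA, target gene) pairs from one source."""

    source_name: str
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        mirnas = {m for m, _ in self.pairs}
        genes = {g for _, g in self.pairs}
        for m, g in self.pairs:
            if not m or not g or m != m.strip() or g != g.strip():
                raise ValueError(f"empty or unstripped ID in pair ({m!r}, {g!r})")
        both = mirnas & genes
        if both:
            raise ValueError(
                f"labels appear in both partitions of table "
                f"{self.source_name!r}: {sorted(both)[:5]}"
            )

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.pairs)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def read_interaction_table(path: str | Path, source_name: str | None = None) -> InteractionTable:
    """Read a two-column TSV of (miRNA, gene) pairs.

    An optional single header line is skipped when its first line contains
    the token ``mirna`` (case-insensitive). Duplicate pairs collapse; ID case
    is preserved exactly.

    Raises
    ------
    TableParseError
        If a line does not have exactly two tab-separated fields (the error
        names the 1-based line number) or the file contains no data rows.
    """
    path = Path(path)
    if source_name is None:
        source_name = path.stem
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and any("mirna" in f.strip().lower() for f in fields):
                continue  # header line
            if len(fields) != 2:
                raise TableParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            m, g = fields[0].strip(), fields[1].strip()
            if not m or not g:
                raise TableParseError(f"{path}: line {lineno}: empty ID field")
            pairs.add((m, g))
    if not pairs:
        raise TableParseError(f"{path}: no interaction pairs found")
    return InteractionTable(source_name=source_name, pairs=frozenset(pairs))


def intersect_tables(
    tables: Sequence[InteractionTable], min_sources: int | None = None
) -> InteractionTable:
    """Keep pairs supported by at least ``min_sources`` tables.

    The default requires support in every supplied table, i.e. the strict
    intersection across source databases. ``min_sources=1`` yields the union.
    """
    if not tables:
        raise ValueError("need at least one interaction table")
    if min_sources is None:
        min_sources = len(tables)
    if not 1 <= min_sources <= len(tables):
        raise ValueError(
            f"min_sources={min_sources} out of range [1, {len(tables)}]"
        )
    counts: Counter[tuple[str, str]] = Counter()
    for t in tables:
        counts.update(t.pairs)
    kept = frozenset(p for p, c in counts.items() if c >= min_sources)
    return InteractionTable(source_name="intersection", pairs=kept)


@dataclass(frozen=True)
class BipartiteNetwork:
    """A bipartite miRNA-mRNA graph with its random-walk transition matrix.

    Node order is deterministic: miRNAs first, then genes, each partition
    sorted lexicographically, so matrices are reproducible across runs.

    Attributes
    ----------
    mirna_nodes, gene_nodes : tuple of str
        The two partitions, in canonical order.
    edges : frozenset of (mirna, gene)
        Undirected cross-partition edges.
    adjacency : scipy.sparse.csr_array
        |V| x |V| binary symmetric matrix over the concatenated node order.
    transition : scipy.sparse.csr_array
        Column-normalized adjacency M. Columns of isolated (degree-0) nodes
        are zero here; the walker treats them as full teleport back to the
        restart distribution, which keeps every effective column stochastic.
    """

    mirna_nodes: tuple[str, ...]
    gene_nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    adjacency: sp.csr_array = field(repr=False)
    transition: sp.csr_array = field(repr=False)

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.mirna_nodes + self.gene_nodes

    @property
    def n_nodes(self) -> int:
        return len(self.mirna_nodes) + len(self.gene_nodes)

    @property
    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=0)).ravel().astype(int)

    @property
    def dangling(self) -> np.ndarray:
        """Boolean mask of degree-0 nodes (full-teleport columns)."""
        return self.degrees == 0

    @property
    def partition(self) -> np.ndarray:
        """Array of 'mirna' / 'gene' labels aligned with the node order."""
        return np.array(
            ["mirna"] * len(self.mirna_nodes) + ["gene"] * len(self.gene_nodes)
        )

    def is_mirna(self, label: str) -> bool:
        return label in set(self.mirna_nodes)


def _from_edges(
    edges: Iterable[tuple[str, str]],
    mirna_nodes: Iterable[str],
    gene_nodes: Iterable[str],
) -> BipartiteNetwork:
    """Assemble matrices for given node sets; allows isolated nodes."""
    mirnas = tuple(sorted(set(mirna_nodes)))
    genes = tuple(sorted(set(gene_nodes)))
    both = set(mirnas) & set(genes)
    if both:
        raise ValueError(f"labels in both partitions: {sorted(both)[:5]}")
    edge_set = frozenset(edges)
    idx = {n: i for i, n in enumerate(mirnas + genes)}
    n = len(mirnas) + len(genes)
    rows, cols = [], []
    for m, g in edge_set:
        i, j = idx[m], idx[g]
        rows += [i, j]
        cols += [j, i]
    data = np.ones(len(rows))
    adjacency = sp.csr_array(
        sp.coo_array((data, (rows, cols)), shape=(n, n))
    )
    adjacency.data[:] = 1.0  # binary even if an edge were listed twice
    deg = np.asarray(adjacency.sum(axis=0)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    transition = sp.csr_array(adjacency @ sp.diags_array(inv))
    return BipartiteNetwork(
        mirna_nodes=mirnas,
        gene_nodes=genes,
        edges=edge_set,
        adjacency=adjacency,
        transition=transition,
    )


def build_network(table: InteractionTable) -> BipartiteNetwork:
    """Build the bipartite network from an interaction table.

    Every column of the transition matrix sums to 1 because each node named
    in a pair has degree >= 1.
    """
    if not table.pairs:
        raise ValueError("cannot build a network from an empty pair set")
    return _from_edges(table.pairs, table.mirnas, table.genes)


def load_seed_list(path: str | Path) -> list[str]:
    """Read seed miRNA IDs, one per line; blanks and '#' comments ignored."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s not in seen:
                seen.add(s)
                out.append(s)
    if not out:
        raise ValueError(f"{path}: no seed IDs found")
    return out


def packaged_seed_path() -> Path:
    """Path of the packaged list of 18 literature-curated seed miRNAs
    associated with colorectal-cancer radiosensitivity."""
    return Path(resources.files("seedwalk.data") / "seeds_crcr_table1.txt")


def write_network(network: BipartiteNetwork, edge_path: str | Path,
                  sidecar_path: str | Path | None = None) -> None:
    """Write an edge-list TSV plus a JSON sidecar with the node partitions."""
    edge_path = Path(edge_path)
    if sidecar_path is None:
        sidecar_path = edge_path.with_suffix(".json")
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("mirna\tgene\n")
        for m, g in sorted(network.edges):
            fh.write(f"{m}\t{g}\n")
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(
            {"mirna_nodes": list(network.mirna_nodes),
             "gene_nodes": list(network.gene_nodes)},
            fh, indent=1,
        )
        fh.write("\n")


def load_network(edge_path: str | Path,
                 sidecar_path: str | Path | None = None) -> BipartiteNetwork:
    """Inverse of :func:`write_network`. The sidecar restores isolated nodes
    and partition membership; without it both are inferred from the edges."""
    edge_path = Path(edge_path)
    table = read_interaction_table(edge_path, source_name=edge_path.stem)
    if sidecar_path is None:
        candidate = edge_path.with_suffix(".json")
        sidecar_path = candidate if candidate.exists() else None
    if sidecar_path is None:
        return build_network(table)
    with open(sidecar_path, encoding="utf-8") as fh:
        sidecar = json.load(fh)
    return _from_edges(table.pairs, sidecar["mirna_nodes"], sidecar["gene_nodes"])
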