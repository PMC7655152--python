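"""Synthetic inputs with planted structure for every pipeline stage.

The network generator emulates the situation the analysis assumes: a sparse
bipartite miRNA-target network in which a group of "related" miRNAs shares
target genes with a set of seed miRNAs, against a background of miRNAs with
unstructured targeting. Each seed owns a private target block and all seeds
share a common target pool; a related miRNA hits each seed-target gene with
probability ``shared_target_prob``, while every other miRNA-gene pair (for
related and background miRNAs alike) carries the ``background_prob`` edge
probability. Setting ``shared_target_prob`` equal to ``background_prob``
therefore removes the planted signal entirely, which is the null condition
used for calibration checks.

The expression generator emulates a two-group qPCR comparison: per-sample
dCt values are Gaussian with a mean shift ``delta_dct`` between groups
(lower dCt = higher expression in the sensitive group), which gives the
closed-form discrimination AUC = Phi(delta / (sigma * sqrt(2))) used as an
oracle in tests.

Both generators are deterministic functions of their ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import AnnotationSet, write_gmt
from .network import BipartiteNetwork, _from_edges

__all__ = ["NetworkGenConfig", "ExpressionGenConfig", "generate_network",
           "generate_ct_table", "write_fixture"]


@dataclass(frozen=True)
class NetworkGenConfig:
    """Planted bipartite network parameters.

    Defaults give a 520-node network (120 miRNAs, 400 genes) with 10 seeds,
    20 planted related miRNAs, and a background edge density of 1%, sized so
    the full pipeline runs in seconds.
    """

    n_mirna: int = 120
    n_gene: int = 400
    n_seed: int = 10
    n_related: int = 20
    shared_target_prob: float = 0.15
    background_prob: float = 0.01
    rng_seed: int = 7
    private_targets_per_seed: int = 5
    shared_pool_size: int = 30

    def __post_init__(self) -> None:
        if self.n_seed + self.n_related > self.n_mirna:
            raise ValueError("n_seed + n_related exceeds n_mirna")
        if min(self.n_mirna, self.n_gene, self.n_seed) < 1:
            raise ValueError("n_mirna, n_gene and n_seed must be positive")
        if self.n_related < 0:
            raise ValueError("n_related must be >= 0")
        for name in ("shared_target_prob", "background_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        need = self.n_seed * self.private_targets_per_seed + self.shared_pool_size
        if need > self.n_gene:
            raise ValueError(
                f"seed target blocks need {need} genes but n_gene={self.n_gene}"
            )


@dataclass(frozen=True)
class ExpressionGenConfig:
    """Two-group qPCR Ct generator parameters (cycles)."""

    n_per_group: int = 9
    delta_dct: float = 1.5
    sigma: float = 1.0
    rng_seed: int = 7
    baseline_dct: float = 5.0
    reference_ct: float = 18.0
    reference_jitter: float = 0.1
    case_group: str = "sensitive"
    control_group: str = "resistant"

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _labels(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(config: NetworkGenConfig = NetworkGenConfig()
                     ) -> tuple[BipartiteNetwork, dict[str, list[str]]]:
    """Sample a planted bipartite network.

    Returns the network and a truth map with keys ``seeds``, ``related``
    and ``background``. Isolated nodes are re-attached by drawing one edge
    from their positive-probability pairs; a node whose every pair
    probability is zero (e.g. background miRNAs when background_prob=0)
    legitimately stays isolated and is handled by the walker's dangling-node
    teleport.
    """
    rng = np.random.default_rng(config.rng_seed)
    mirnas = _labels("mir-sim-", config.n_mirna)
    genes = _labels("GENE", config.n_gene)
    seeds = mirnas[: config.n_seed]
    related = mirnas[config.n_seed: config.n_seed + config.n_related]
    background = mirnas[config.n_seed + config.n_related:]

    b = config.private_targets_per_seed
    blocks = {s: genes[i * b: (i + 1) * b] for i, s in enumerate(seeds)}
    pool = genes[config.n_seed * b: config.n_seed * b + config.shared_pool_size]
    seed_target_union = sorted({g for gs in blocks.values() for g in gs} | set(pool))
    seed_target_mask = np.isin(genes, seed_target_union)

    # per-pair edge probabilities by role; seed rows are deterministic
    # (exactly their private block plus the shared pool)
    prob = np.full((config.n_mirna, config.n_gene), config.background_prob)
    rel_lo = config.n_seed
    rel_hi = config.n_seed + config.n_related
    prob[rel_lo:rel_hi, seed_target_mask] = config.shared_target_prob
    prob[:rel_lo, :] = 0.0
    adj = rng.random((config.n_mirna, config.n_gene)) < prob
    gene_pos = {g: j for j, g in enumerate(genes)}
    for i, s in enumerate(seeds):
        for g in blocks[s]:
            adj[i, gene_pos[g]] = True
        for g in pool:
            adj[i, gene_pos[g]] = True

    # re-attach isolated nodes among their positive-probability pairs
    for i in range(config.n_mirna):
        if not adj[i].any():
            pool_j = np.flatnonzero(prob[i] > 0)
            if pool_j.size:
                adj[i, rng.choice(pool_j)] = True
    for j in range(config.n_gene):
        if not adj[:, j].any():
            pool_i = np.flatnonzero(prob[:, j] > 0)
            if pool_i.size:
                adj[rng.choice(pool_i), j] = True

    edges = {(mirnas[i], genes[j]) for i, j in zip(*np.nonzero(adj))}
    network = _from_edges(edges, mirnas, genes)
    truth = {"seeds": seeds, "related": related, "background": background}
    return network, truth


def generate_ct_table(config: ExpressionGenConfig = ExpressionGenConfig()) -> pd.DataFrame:
    """Sample a two-group qPCR Ct table.

    Control-group dCt ~ N(baseline, sigma^2); case-group dCt is shifted down
    by ``delta_dct`` (higher expression). The reference-gene Ct is a
    plausible constant plus small jitter, and Ct(target) = Ct(ref) + dCt.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_per_group
    rows = []
    for group, mu in (
        (config.control_group, config.baseline_dct),
        (config.case_group, config.baseline_dct - config.delta_dct),
    ):
        dct = rng.normal(mu, config.sigma, size=n)
        ref = config.reference_ct + rng.normal(0.0, config.reference_jitter, size=n)
        for i in range(n):
            rows.append((f"{group}-{i + 1:02d}", group,
                         ref[i] + dct[i], ref[i]))
    return pd.DataFrame(rows, columns=["sample_id", "group",
                                       "ct_target", "ct_reference"])


def _decoy_pairs(rng: np.random.Generator, mirnas: list[str], genes: list[str],
                 forbidden: set[tuple[str, str]], count: int) -> set[tuple[str, str]]:
    decoys: set[tuple[str, str]] = set()
    guard = 0
    while len(decoys) < count and guard < 100 * count + 100:
        pair = (mirnas[rng.integers(len(mirnas))], genes[rng.integers(len(genes))])
        if pair not in forbidden and pair not in decoys:
            decoys.add(pair)
        guard += 1
    return decoys


def write_fixture(
    out_dir: str | Path,
    net_config: NetworkGenConfig = NetworkGenConfig(),
    expr_config: ExpressionGenConfig = ExpressionGenConfig(),
    n_sources: int = 3,
    decoy_frac: float = 0.3,
) -> dict[str, Path]:
    """Write a complete synthetic input set in the formats the readers consume.

    Produces ``n_sources`` pseudo-database interaction tables that all
    contain every true edge plus source-specific decoy pairs (so the strict
    intersection recovers the planted network exactly), the seed list, GMT
    annotations derived from the planted target blocks, and a Ct table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    network, truth = generate_network(net_config)
    rng = np.random.default_rng(net_config.rng_seed + 1)
    mirnas, genes = list(network.mirna_nodes), list(network.gene_nodes)
    paths: dict[str, Path] = {}

    n_decoys = int(decoy_frac * len(network.edges))
    for s in range(n_sources):
        decoys = _decoy_pairs(rng, mirnas, genes, set(network.edges), n_decoys)
        path = out_dir / f"source_{s + 1}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("mirna\tgene\n")
            for m, g in sorted(set(network.edges) | decoys):
                fh.write(f"{m}\t{g}\n")
        paths[f"source_{s + 1}"] = path

    seed_path = out_dir / "seeds.txt"
    seed_path.write_text("".join(f"{s}\n" for s in truth["seeds"]), encoding="utf-8")
    paths["seeds"] = seed_path

    # annotation terms from the planted blocks plus random same-size decoy terms
    b = net_config.private_targets_per_seed
    terms: dict[str, frozenset[str]] = {}
    for i, s in enumerate(truth["seeds"]):
        terms[f"block_{s}"] = frozenset(genes[i * b: (i + 1) * b])
    pool = genes[net_config.n_seed * b:
                 net_config.n_seed * b + net_config.shared_pool_size]
    terms["shared_pool"] = frozenset(pool)
    for t in range(10):
        size = int(rng.integers(5, 31))
        members = rng.choice(len(genes), size=size, replace=False)
        terms[f"random_{t + 1:02d}"] = frozenset(genes[j] for j in members)
    gmt_path = out_dir / "annotations.gmt"
    write_gmt(AnnotationSet(terms=terms, namespace="BP"), gmt_path)
    paths["annotations"] = gmt_path

    ct_path = out_dir / "ct_table.tsv"
    generate_ct_table(expr_config).to_csv(ct_path, sep="\t", index=False,
                                          float_format="%.6f")
    paths["ct_table"] = ct_path

    truth_path = out_dir / "truth.json"
    import json

    truth_path.write_text(json.dumps(truth, indent=1) + "\n", encoding="utf-8")
    paths["truth"] = truth_path
    return paths
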