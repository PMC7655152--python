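"""Random walk with restart (RWR) on the bipartite network.

The walker starts from a restart distribution P0 putting mass 1/N on each of
N seed miRNAs and iterates

    P_{i+1} = (1 - r) M P_i + r P0

where M is the column-normalized adjacency matrix and r the restart
probability (0.8 by default, weighting proximity to the seeds heavily).
Iteration stops when the L1 norm of successive differences falls below the
tolerance. The fixed point solves (I - (1-r) M) p = r P0, which
:func:`rwr_closed_form` computes directly as an independent dense oracle.

Isolated nodes have a zero column in M; the walker treats such a column as a
full teleport back to P0, so probability mass is conserved at every step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import BipartiteNetwork

__all__ = ["RWRConfig", "ScoreVector", "make_seed_vector", "run_rwr",
           "rwr_closed_form", "write_scores"]

#: dense-solve guard for the closed-form oracle
_CLOSED_FORM_MAX_NODES = 2000


@dataclass(frozen=True)
class RWRConfig:
    """Walk parameters: restart probability, L1 tolerance, iteration cap."""

    restart_prob: float = 0.8
    tol: float = 1e-6
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob <= 1.0:
            raise ValueError(f"restart_prob must be in (0, 1], got {self.restart_prob}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ScoreVector:
    """Per-node probabilities aligned with a network's canonical node order."""

    values: np.ndarray
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def make_seed_vector(network: BipartiteNetwork, seeds: set[str] | list[str]) -> ScoreVector:
    """Restart distribution: mass 1/N on each of the N matched seed miRNAs.

    Seeds absent from the miRNA partition are dropped with a warning; if none
    match, a ValueError lists the unmatched IDs.
    """
    seeds = list(dict.fromkeys(seeds))
    if not seeds:
        raise ValueError("empty seed set")
    mirna_set = set(network.mirna_nodes)
    matched = [s for s in seeds if s in mirna_set]
    missing = [s for s in seeds if s not in mirna_set]
    if not matched:
        raise ValueError(f"no seed matches a miRNA node: {missing}")
    if missing:
        warnings.warn(
            f"{len(missing)} seed(s) not in the miRNA partition, dropped: {missing}",
            stacklevel=2,
        )
    idx = network.node_index
    p0 = np.zeros(network.n_nodes)
    for s in matched:
        p0[idx[s]] = 1.0 / len(matched)
    return ScoreVector(values=p0)


def _propagate(transition, dangling: np.ndarray, p0: np.ndarray,
               p: np.ndarray, r: float) -> np.ndarray:
    """One synchronous update; dangling columns teleport their mass to p0.

    Works on 1-D vectors or on (n, B) column stacks of independent walks.
    """
    moved = transition @ p
    lost = p[dangling].sum(axis=0)  # scalar or (B,): mass on dangling nodes
    if np.ndim(p) == 2:
        moved = moved + p0 * lost[None, :]
    elif lost:
        moved = moved + p0 * lost
    return (1.0 - r) * moved + r * p0


def run_rwr(network: BipartiteNetwork, p0: ScoreVector,
            config: RWRConfig = RWRConfig()) -> ScoreVector:
    """Iterate the walk to its stationary distribution.

    Returns the final vector with the iteration count; if the cap is hit
    first, the result is returned with ``converged=False`` and a warning.
    """
    start = np.asarray(p0.values, dtype=float)
    if start.shape != (network.n_nodes,):
        raise ValueError(
            f"p0 has shape {start.shape}, network has {network.n_nodes} nodes"
        )
    out = _iterate(network, start, config)
    values, n_iter, converged = out
    if not converged:
        warnings.warn(
            f"RWR did not converge within {config.max_iter} iterations "
            f"(tol={config.tol})",
            stacklevel=2,
        )
    return ScoreVector(values=values, n_iter=n_iter, converged=converged)


def _iterate(network: BipartiteNetwork, p0: np.ndarray, config: RWRConfig):
    r = config.restart_prob
    dangling = network.dangling
    p = p0.copy()
    for i in range(1, config.max_iter + 1):
        p_next = _propagate(network.transition, dangling, p0, p, r)
        delta = np.abs(p_next - p).sum(axis=0)
        p = p_next
        if np.max(delta) < config.tol:
            return p, i, True
    return p, config.max_iter, False


def run_rwr_batch(network: BipartiteNetwork, p0_columns: np.ndarray,
                  config: RWRConfig = RWRConfig()) -> tuple[np.ndarray, int, bool]:
    """Run independent walks for each column of ``p0_columns`` at once.

    Used by the permutation test, where hundreds of pseudo-seed restarts
    share the same transition matrix. Stops when every column's L1 change is
    below tolerance. Returns (stationary columns, n_iter, converged).
    """
    p0 = np.asarray(p0_columns, dtype=float)
    if p0.ndim != 2 or p0.shape[0] != network.n_nodes:
        raise ValueError("p0_columns must be (n_nodes, B)")
    r = config.restart_prob
    dangling = network.dangling
    p = p0.copy()
    for i in range(1, config.max_iter + 1):
        p_next = _propagate(network.transition, dangling, p0, p, r)
        delta = np.abs(p_next - p).sum(axis=0)
        p = p_next
        if delta.max() < config.tol:
            return p, i, True
    return p, config.max_iter, False


def rwr_closed_form(network: BipartiteNetwork, p0: ScoreVector,
                    restart_prob: float = 0.8) -> ScoreVector:
    """Exact stationary distribution by dense linear solve.

    Solves p = r (I - (1-r) M_eff)^{-1} P0, with dangling columns of M
    replaced by P0 (full teleport). For r > 0 the system matrix is strictly
    diagonally dominant in the column-sum sense and never singular. Guarded
    to networks of <= 2000 nodes; meant as a test oracle, not the production
    path.
    """
    if not 0.0 < restart_prob <= 1.0:
        raise ValueError(f"restart_prob must be in (0, 1], got {restart_prob}")
    n = network.n_nodes
    if n > _CLOSED_FORM_MAX_NODES:
        raise ValueError(f"closed form limited to {_CLOSED_FORM_MAX_NODES} nodes, got {n}")
    start = np.asarray(p0.values, dtype=float)
    m = network.transition.toarray()
    dangling = network.dangling
    if dangling.any():
        m[:, dangling] = start[:, None]
    a = np.eye(n) - (1.0 - restart_prob) * m
    values = np.linalg.solve(a, restart_prob * start)
    return ScoreVector(values=values, n_iter=0, converged=True)


def write_scores(network: BipartiteNetwork, scores: ScoreVector,
                 path) -> None:
    """Export (node_id, partition, score) TSV sorted by descending score."""
    order = np.argsort(-scores.values, kind="stable")
    nodes = network.nodes
    part = network.partition
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_id\tpartition\tscore\n")
        for i in order:
            fh.write(f"{nodes[i]}\t{part[i]}\t{scores.values[i]:.10g}\n")
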