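"""Permutation-based significance and FDR selection for candidate miRNAs.

The observed RWR score of each non-seed miRNA is compared against a null
distribution obtained by re-running the walk from random pseudo-seed sets of
the same cardinality (1000 permutations by default). Empirical p-values use
the add-one estimator p = (1 + #{null >= observed}) / (B + 1), ties counted
as exceeding (conservative), and are adjusted by Benjamini-Hochberg; a
candidate is selected when its q-value is strictly below alpha (0.05).

The choice of null — resampled seed sets over a fixed topology — preserves
the two quantities the analysis holds fixed, the network and the seed-set
size. A degree-matched variant draws each pseudo-seed from miRNAs of similar
degree to one true seed, guarding against degree-driven score inflation.

One subtlety: a candidate drawn as its own pseudo-seed receives restart
mass r/N directly, a score incomparable with propagation-driven scores; if
such draws entered its null, no empirical p-value could fall below the
self-draw probability k/n_mirna. Permutations in which the candidate itself
was a pseudo-seed are therefore excluded from that candidate's null (the
matrix carries NaN there and the per-candidate B shrinks accordingly).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .network import BipartiteNetwork
from .rwr import RWRConfig, ScoreVector, run_rwr_batch

__all__ = ["permutation_null", "empirical_pvalues", "bh_fdr",
           "select_candidates", "candidate_table", "write_candidates"]


def _pseudo_seed_sets(network: BipartiteNetwork, seeds: list[str],
                      n_perm: int, rng: np.random.Generator,
                      null_model: str) -> list[list[int]]:
    idx = network.node_index
    mirna_idx = np.array([idx[m] for m in network.mirna_nodes])
    k = len(seeds)
    if k > len(mirna_idx):
        raise ValueError(f"{k} seeds but only {len(mirna_idx)} miRNA nodes")
    if null_model == "uniform":
        return [list(rng.choice(mirna_idx, size=k, replace=False))
                for _ in range(n_perm)]
    if null_model == "degree_matched":
        deg = network.degrees
        seed_deg = [deg[idx[s]] for s in seeds]
        order = np.argsort(deg[mirna_idx], kind="stable")
        sorted_idx = mirna_idx[order]
        sorted_deg = deg[sorted_idx]
        # window of the 10 nearest-degree miRNAs around each seed's degree
        window = max(10, k)
        sets = []
        for _ in range(n_perm):
            chosen: list[int] = []
            taken: set[int] = set()
            for d in seed_deg:
                pos = np.searchsorted(sorted_deg, d)
                lo = max(0, pos - window // 2)
                hi = min(len(sorted_idx), lo + window)
                lo = max(0, hi - window)
                pool = [int(j) for j in sorted_idx[lo:hi] if int(j) not in taken]
                pick = int(rng.choice(pool))
                chosen.append(pick)
                taken.add(pick)
            sets.append(chosen)
        return sets
    raise ValueError(f"unknown null_model {null_model!r}")


def permutation_null(
    network: BipartiteNetwork,
    seeds: list[str] | set[str],
    n_perm: int = 1000,
    config: RWRConfig = RWRConfig(),
    rng_seed: int = 0,
    null_model: str = "uniform",
    batch_size: int = 100,
) -> tuple[np.ndarray, list[str]]:
    """Null score matrix from random pseudo-seed restarts.

    Each of the ``n_perm`` iterations draws a pseudo-seed set of the same
    size as ``seeds`` from the miRNA partition, runs the walk with identical
    parameters, and records the scores of every candidate (non-seed) miRNA.

    Returns
    -------
    (null_matrix, candidates)
        ``null_matrix`` has shape (n_perm, n_candidates); columns align with
        ``candidates``, the non-seed miRNAs in canonical node order. Entries
        where the candidate itself was drawn as a pseudo-seed are NaN and
        ignored by :func:`empirical_pvalues`.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    seeds = [s for s in network.mirna_nodes if s in set(seeds)]
    if not seeds:
        raise ValueError("no seed matches a miRNA node")
    candidates = [m for m in network.mirna_nodes if m not in set(seeds)]
    idx = network.node_index
    cand_idx = np.array([idx[m] for m in candidates])
    rng = np.random.default_rng(rng_seed)
    seed_sets = _pseudo_seed_sets(network, seeds, n_perm, rng, null_model)

    null = np.empty((n_perm, len(candidates)))
    k = len(seeds)
    for start in range(0, n_perm, batch_size):
        chunk = seed_sets[start:start + batch_size]
        p0 = np.zeros((network.n_nodes, len(chunk)))
        for b, s in enumerate(chunk):
            p0[s, b] = 1.0 / k
        stationary, _, _ = run_rwr_batch(network, p0, config)
        block = stationary[cand_idx, :].T
        for b, s in enumerate(chunk):
            seeded = np.isin(cand_idx, s)
            block[b, seeded] = np.nan
        null[start:start + len(chunk), :] = block
    return null, candidates


def empirical_pvalues(observed: np.ndarray, null_matrix: np.ndarray) -> np.ndarray:
    """Add-one empirical p-values, ties counted as >= (conservative).

    p_j = (1 + #{b : null[b, j] >= observed[j]}) / (B_j + 1), where B_j
    counts the non-NaN null entries for candidate j (NaN marks permutations
    where j itself was a pseudo-seed).
    """
    observed = np.asarray(observed, dtype=float)
    null_matrix = np.asarray(null_matrix, dtype=float)
    if null_matrix.ndim != 2 or null_matrix.shape[1] != observed.shape[0]:
        raise ValueError(
            f"null matrix shape {null_matrix.shape} does not align with "
            f"{observed.shape[0]} candidates"
        )
    valid = ~np.isnan(null_matrix)
    b_eff = valid.sum(axis=0)
    if np.any(b_eff == 0):
        raise ValueError("a candidate has no valid null permutations")
    with np.errstate(invalid="ignore"):
        exceed = np.where(valid, null_matrix >= observed[None, :], False).sum(axis=0)
    return (1.0 + exceed) / (b_eff + 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def candidate_table(
    candidates: list[str],
    observed: np.ndarray,
    null_matrix: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assemble the per-candidate table: score, empirical p, q, selection."""
    emp_p = empirical_pvalues(observed, null_matrix)
    q = bh_fdr(emp_p)
    df = pd.DataFrame(
        {
            "mirna_id": candidates,
            "score": np.asarray(observed, dtype=float),
            "emp_p": emp_p,
            "q_value": q,
        }
    )
    df = df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    return select_candidates(df, alpha=alpha)


def observed_candidate_scores(network: BipartiteNetwork, scores: ScoreVector,
                              candidates: list[str]) -> np.ndarray:
    idx = network.node_index
    return scores.values[[idx[m] for m in candidates]]


def select_candidates(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag candidates with q-value strictly below alpha as selected."""
    out = table.copy()
    out["selected"] = out["q_value"] < alpha
    return out


def write_candidates(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
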