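"""Over-representation analysis of target gene sets against annotations.

A local hypergeometric test replaces the web-service enrichment step so the
stage runs offline and is unit-testable: for each annotation term the
upper-tail probability P[X >= overlap] is computed for the overlap between
the query gene set and the term's genes within a stated universe, followed
by Benjamini-Hochberg adjustment (terms with q < alpha are significant).

Annotations are read from GMT files (term TAB description TAB gene...), the
de-facto standard for gene-set collections, so public GO / pathway exports
drop in directly.

The agreement between two enrichment result sets (e.g. terms enriched in the
targets of known seed miRNAs vs. newly prioritized miRNAs) is summarized by
an overlap rate, either Jaccard (intersection over union) or relative to a
reference set; both conventions are reported because published overlap
percentages rarely state their denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .significance import bh_fdr

__all__ = ["AnnotationSet", "read_gmt", "hypergeometric_ora", "overlap_rate",
           "write_enrichment"]


@dataclass(frozen=True)
class AnnotationSet:
    """Named gene sets within one namespace ('BP', 'pathway', ...)."""

    terms: dict[str, frozenset[str]]
    namespace: str = "BP"

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")

    def restricted_to(self, universe: set[str]) -> "AnnotationSet":
        kept = {
            t: frozenset(g & universe)
            for t, g in self.terms.items()
            if g & universe
        }
        return AnnotationSet(terms=kept, namespace=self.namespace)


def read_gmt(path: str | Path, namespace: str = "BP") -> AnnotationSet:
    """Read a GMT file: term_id TAB description TAB gene [TAB gene ...]."""
    terms: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT rows need term, description "
                    "and at least one gene"
                )
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}: line {lineno}: no genes for {fields[0]!r}")
            terms[fields[0].strip()] = genes
    if not terms:
        raise ValueError(f"{path}: empty GMT file")
    return AnnotationSet(terms=terms, namespace=namespace)


def write_gmt(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(annotations.terms):
            genes = "\t".join(sorted(annotations.terms[term]))
            fh.write(f"{term}\t{annotations.namespace}\t{genes}\n")


def hypergeometric_ora(
    query: set[str],
    annotations: AnnotationSet,
    universe: set[str],
    alpha: float = 0.05,
    keep_zero_overlap: bool = True,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of each term against the query.

    Terms are intersected with the universe before testing. Zero-overlap
    terms are retained with p = 1 unless ``keep_zero_overlap`` is False.
    """
    query = set(query)
    universe = set(universe)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError(
            f"{len(query - universe)} query genes outside the universe"
        )
    restricted = annotations.restricted_to(universe)
    rows = []
    n_u, n_q = len(universe), len(query)
    for term in sorted(restricted.terms):
        genes = restricted.terms[term]
        overlap = len(query & genes)
        if overlap == 0 and not keep_zero_overlap:
            continue
        p = float(hypergeom.sf(overlap - 1, n_u, len(genes), n_q))
        rows.append((term, overlap, len(genes), n_q, n_u, min(p, 1.0)))
    df = pd.DataFrame(
        rows,
        columns=["term_id", "overlap", "term_size", "query_size",
                 "universe_size", "p"],
    )
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else df["p"]
    df["significant"] = df["q"] < alpha
    return df.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)


def overlap_rate(a: set[str], b: set[str], method: str = "jaccard") -> float:
    """Overlap between two significant-term sets.

    ``jaccard``: |a & b| / |a | b|; ``reference``: |a & b| / |a| (share of
    the first, reference, set recovered by the second).
    """
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("overlap rate undefined for two empty sets")
    inter = len(a & b)
    if method == "jaccard":
        return inter / len(a | b)
    if method == "reference":
        if not a:
            raise ValueError("reference set is empty")
        return inter / len(a)
    raise ValueError(f"unknown method {method!r}")


def write_enrichment(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", index=False, float_format="%.10g")
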