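"""End-to-end orchestration of the discovery pipeline.

Stages: read and intersect the interaction tables, build the bipartite
network, propagate from the seed miRNAs (RWR), score significance against a
permutation null with BH-FDR selection, extract the selected candidates'
sub-network and call hubs by top-k centrality overlap, then optionally run
annotation enrichment of seed-target vs candidate-target genes and the
qPCR validation statistics.

Every stage writes its table to ``output_dir``; a run manifest records all
parameters, stage outputs with SHA-256 checksums, and summary counts. The
manifest contains no timestamps, so two runs with identical configuration
and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

from . import enrichment as enr
from . import network as net
from . import rwr
from . import significance as sig
from . import topology as topo
from . import validation as val

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("seedwalk")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and offending input."""


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Defaults mirror the published analysis settings: restart probability
    0.8, L1 tolerance 1e-6, 1000 permutations, FDR threshold 0.05, top-10
    centrality overlap for hub calling.
    """

    interaction_tables: list[str]
    seed_list: str
    output_dir: str
    annotation_gmt: str | None = None
    ct_table: str | None = None
    min_sources: int | None = None
    restart_prob: float = 0.8
    tol: float = 1e-6
    max_iter: int = 10_000
    n_perm: int = 1000
    alpha: float = 0.05
    top_k: int = 10
    null_model: str = "uniform"
    rng_seed: int = 0
    calibrator_group: str = "resistant"
    case_group: str = "sensitive"

    def __post_init__(self) -> None:
        if not self.interaction_tables:
            raise ValueError("at least one interaction table is required")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        for p in [*self.interaction_tables, self.seed_list,
                  self.annotation_gmt, self.ct_table]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def rwr_config(self) -> rwr.RWRConfig:
        return rwr.RWRConfig(restart_prob=self.restart_prob, tol=self.tol,
                             max_iter=self.max_iter)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to
    ``output_dir/manifest.json``)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {k: v for k, v in asdict(config).items()},
        "stages": [],
        "outputs": {},
        "counts": {},
    }

    def record(stage: str, path: Path) -> None:
        if stage not in manifest["stages"]:
            manifest["stages"].append(stage)
        manifest["outputs"][path.name] = _sha256(path)

    def run_stage(name: str, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # annotate and re-raise
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return result

    # --- network construction -------------------------------------------
    tables = run_stage(
        "network", lambda: [net.read_interaction_table(p)
                            for p in config.interaction_tables]
    )
    merged = run_stage("network", net.intersect_tables, tables,
                       config.min_sources)
    network = run_stage("network", net.build_network, merged)
    net.write_network(network, out / "network.tsv", out / "network.json")
    record("network", out / "network.tsv")
    record("network", out / "network.json")
    manifest["counts"].update(
        n_mirna=len(network.mirna_nodes),
        n_gene=len(network.gene_nodes),
        n_edges=len(network.edges),
    )
    log.info("network: %d miRNAs, %d genes, %d edges",
             len(network.mirna_nodes), len(network.gene_nodes),
             len(network.edges))

    # --- propagation -----------------------------------------------------
    seeds = run_stage("rwr", net.load_seed_list, config.seed_list)
    p0 = run_stage("rwr", rwr.make_seed_vector, network, seeds)
    scores = run_stage("rwr", rwr.run_rwr, network, p0, config.rwr_config())
    rwr.write_scores(network, scores, out / "scores.tsv")
    record("rwr", out / "scores.tsv")
    log.info("rwr: converged=%s after %d iterations", scores.converged,
             scores.n_iter)

    # --- significance ----------------------------------------------------
    null, candidates = run_stage(
        "significance", sig.permutation_null, network, seeds,
        n_perm=config.n_perm, config=config.rwr_config(),
        rng_seed=config.rng_seed, null_model=config.null_model,
    )
    observed = sig.observed_candidate_scores(network, scores, candidates)
    cand = run_stage("significance", sig.candidate_table, candidates,
                     observed, null, config.alpha)
    sig.write_candidates(cand, out / "candidates.tsv")
    record("significance", out / "candidates.tsv")
    selected = list(cand.loc[cand["selected"], "mirna_id"])
    manifest["counts"]["n_candidates"] = len(candidates)
    manifest["counts"]["n_selected"] = len(selected)
    log.info("significance: %d / %d candidates selected at FDR < %s",
             len(selected), len(candidates), config.alpha)

    # --- topology --------------------------------------------------------
    hubs: list[str] = []
    if selected:
        sub = run_stage("topology", topo.extract_subnetwork, network, selected)
        cent = run_stage("topology", topo.centralities, sub)
        hub_set, cent = run_stage("topology", topo.top_k_overlap, cent,
                                  config.top_k, set(selected))
        hubs = sorted(hub_set)
        topo.write_centralities(cent, out / "centrality.tsv")
        (out / "hubs.txt").write_text("".join(f"{h}\n" for h in hubs),
                                      encoding="utf-8")
        topo.write_graphml(sub, out / "subnetwork.graphml")
        for name in ("centrality.tsv", "hubs.txt", "subnetwork.graphml"):
            record("topology", out / name)
        manifest["counts"]["subnetwork_summary"] = topo.summarize_subnetwork(cent)
    else:
        manifest["counts"]["subnetwork_summary"] = None
        log.warning("topology skipped: no candidate passed selection")
    manifest["counts"]["hubs"] = hubs

    # --- enrichment (optional) -------------------------------------------
    if config.annotation_gmt is not None and selected:
        annotations = run_stage("enrichment", enr.read_gmt, config.annotation_gmt)
        universe = set(network.gene_nodes)
        seed_targets = {g for m, g in network.edges if m in set(seeds)}
        cand_targets = {g for m, g in network.edges if m in set(selected)}
        res_seed = run_stage("enrichment", enr.hypergeometric_ora,
                             seed_targets, annotations, universe, config.alpha)
        res_cand = run_stage("enrichment", enr.hypergeometric_ora,
                             cand_targets, annotations, universe, config.alpha)
        enr.write_enrichment(res_seed, out / "enrichment_seed_targets.tsv")
        enr.write_enrichment(res_cand, out / "enrichment_candidate_targets.tsv")
        record("enrichment", out / "enrichment_seed_targets.tsv")
        record("enrichment", out / "enrichment_candidate_targets.tsv")
        sig_seed = set(res_seed.loc[res_seed["significant"], "term_id"])
        sig_cand = set(res_cand.loc[res_cand["significant"], "term_id"])
        if sig_seed or sig_cand:
            rates = {
                "jaccard": enr.overlap_rate(sig_seed, sig_cand, "jaccard"),
                "reference": (enr.overlap_rate(sig_seed, sig_cand, "reference")
                              if sig_seed else None),
            }
        else:
            rates = {"jaccard": None, "reference": None}
        manifest["counts"]["enrichment_overlap"] = rates
        manifest["counts"]["common_targets"] = len(seed_targets & cand_targets)

    # --- validation statistics (optional) ---------------------------------
    if config.ct_table is not None:
        ct = run_stage("validation", val.read_ct_table, config.ct_table)
        rel = run_stage("validation", val.relative_expression, ct,
                        config.calibrator_group)
        rel.to_csv(out / "fold_changes.tsv", sep="\t", index=False,
                   float_format="%.10g")
        record("validation", out / "fold_changes.tsv")
        case = rel.loc[rel["group"] == config.case_group, "dct"]
        ctrl = rel.loc[rel["group"] == config.calibrator_group, "dct"]
        t, p = run_stage("validation", val.compare_groups, case, ctrl)
        # expression scores: -dCt (higher = more expressed)
        auc = run_stage("validation", val.auc_roc, -case.to_numpy(),
                        -ctrl.to_numpy())
        roc = val.roc_points(-case.to_numpy(), -ctrl.to_numpy())
        roc.to_csv(out / "roc_points.tsv", sep="\t", index=False,
                   float_format="%.10g")
        record("validation", out / "roc_points.tsv")
        manifest["counts"]["validation"] = {"t": t, "p": p, "auc": auc}

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
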