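# seedwalk

Network propagation for candidate microRNA discovery on bipartite
miRNA–mRNA networks.

Many traits — here the motivating case is radiosensitivity of colorectal
cancer — have a handful of microRNAs with experimental evidence of
involvement, while hundreds more remain untested. `seedwalk` implements the
standard network-based strategy for extending such a seed list: build a
bipartite miRNA–target network from the intersection of target-prediction
databases, diffuse probability mass from the known seed miRNAs with a
random walk with restart, and flag the non-seed miRNAs whose stationary
score is larger than expected under a permutation null. The selected
candidates' sub-network is then mined for hub miRNAs, and downstream
modules cover annotation enrichment of the target genes and the qPCR
validation statistics (2^−ΔΔCt fold changes, Welch t-test, ROC/AUC).

## Model

Let `M` be the column-normalized adjacency matrix of the undirected
bipartite graph whose edges link miRNAs to their target genes, and let
`P0` put mass `1/N` on each of the `N` seed miRNAs. The walk iterates

```
P_{i+1} = (1 − r) M P_i + r P0
```

until the L1 change between successive vectors falls below a tolerance
(default `1e-6`). The restart probability `r` (default 0.8) keeps the
walker close to the seeds, so the stationary vector scores each node's
proximity to the seed set. The fixed point solves
`p = r (I − (1−r) M)^{-1} P0`, which the package also computes directly as
a dense-solve oracle for testing.

Significance: for each of `B` permutations (default 1000), a pseudo-seed
set of the same size is drawn from the miRNA partition and the walk is
re-run; a candidate's empirical p-value is
`(1 + #{null ≥ observed}) / (B_eff + 1)` (permutations in which the
candidate itself was drawn as a pseudo-seed are excluded from its null),
followed by Benjamini–Hochberg adjustment; candidates with q < 0.05 are
selected. Hubs are the candidates appearing simultaneously in the top-k
(default 10) of degree, closeness (1/Σd convention) and betweenness
(unnormalized Brandes counts) on the candidate sub-network.

A synthetic-data module generates all pipeline inputs with a planted
cluster of miRNAs sharing targets with the seeds, so every stage is
testable without database downloads; the package ships the 18
literature-curated colorectal-cancer radiosensitivity seed IDs as a
fixture for use against real database exports.

## Worked example

```python
from seedwalk import PipelineConfig, run_pipeline, NetworkGenConfig, write_fixture

paths = write_fixture("inputs", NetworkGenConfig(shared_target_prob=0.5, rng_seed=7))
config = PipelineConfig(
    interaction_tables=[str(paths[f"source_{i}"]) for i in (1, 2, 3)],
    seed_list=str(paths["seeds"]),
    annotation_gmt=str(paths["annotations"]),
    ct_table=str(paths["ct_table"]),
    output_dir="out",
    n_perm=1000, top_k=3, rng_seed=1,
)
manifest = run_pipeline(config)
print(manifest["counts"]["hubs"])
print(manifest["counts"]["validation"])
```

prints

```
['mir-sim-022', 'mir-sim-028', 'mir-sim-030']
{'t': -5.6565350890899735, 'p': 5.4812012156903756e-05, 'auc': 1.0}
```

The fixture plants 20 "related" miRNAs that share targets with 10 seeds in
a 120-miRNA × 400-gene network. The pipeline intersects the three
pseudo-database tables, runs the walk, and selects 8 candidates at
FDR < 0.05 — all of them planted; the three hub calls are the candidates
in the top 3 of all three centralities. The head of `out/candidates.tsv`:

```
mirna_id     score     emp_p     q_value   selected
mir-sim-028  0.001163  0.001081  0.015193  True
mir-sim-030  0.001106  0.001099  0.015193  True
mir-sim-022  0.001091  0.001079  0.015193  True
mir-sim-012  0.001076  0.012931  0.109416  False
```

The validation block shows the two-group Ct comparison of the synthetic
plasma table: sensitive samples have significantly lower ΔCt (higher
expression, Welch p ≈ 5e-5) and the expression score separates the groups
with AUC 1.0 at the planted shift of 1.5 cycles.

The same pipeline is available from the shell:

```
seedwalk simulate --out-dir inputs --rng-seed 7
seedwalk run-all --config demo.yaml
```

with subcommands `build-net`, `rwr`, `permute`, `topology`, `enrich` and
`validate` exposing the individual stages.

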