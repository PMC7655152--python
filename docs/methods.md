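# Methods

## Network construction

Interaction tables are two-column TSVs of (miRNA, target gene) pairs, one
per source database. Pairs supported by at least `min_sources` tables are
kept; the default requires support in every table, the strictest reading of
"overlap across databases", and is exposed as configuration because source
databases differ in reliability (an experimentally validated source might
reasonably be privileged with `min_sources = 2` of 3). IDs are opaque,
case-sensitive labels: miRNA nomenclature is messy, and silent
normalization would create false joins; curating IDs is the caller's job.

Node order is canonical — miRNAs before genes, each partition sorted — so
adjacency and transition matrices are bit-reproducible across runs and
platforms. The transition matrix is the column-normalized adjacency;
columns of degree-0 nodes are zero in the stored matrix and treated by the
walker as a full teleport back to the restart distribution, which keeps the
effective operator column-stochastic and conserves probability mass.
Isolated nodes cannot arise from an edge list, but they can arise from
sub-setting or from the synthetic generator's degenerate configurations.

## Random walk with restart

The update `P_{i+1} = (1−r) M P_i + r P0` is iterated synchronously with
sparse matrix-vector products; no randomness is involved. Defaults:
restart probability `r = 0.8` (weighting proximity to the seeds heavily),
L1 tolerance `1e-6`, iteration cap 10 000. Because the map is a contraction
with factor `(1−r)`, an L1 step change below `tol` bounds the L1 distance
to the fixed point by `tol (1−r) / r`, comfortably inside the `1e-5`
agreement the oracle tests demand. Non-convergence at the cap returns the
last iterate flagged `converged=False` with a warning rather than raising:
a nearly converged vector is still interpretable and the flag is recorded.

`rwr_closed_form` solves `(I − (1−r) M) p = r P0` densely (guarded to
2000 nodes). It exists as an independent oracle for the iterative path and
is never used by the pipeline. Scores are computed for all nodes; candidate
ranking downstream restricts to non-seed miRNAs.

A batched variant iterates many restart columns simultaneously against the
shared transition matrix; the permutation test uses it in chunks of 100.

## Permutation significance

The null re-draws pseudo-seed sets of the true cardinality uniformly from
the miRNA partition and re-scores the network, preserving the two fixed
quantities of the analysis: topology and seed-set size. Empirical p-values
use the add-one estimator with ties counted conservatively as exceedances.

Two deliberate refinements:

- **Self-seed exclusion.** A candidate drawn as its own pseudo-seed
  receives restart mass `r/N` directly — orders of magnitude above any
  propagation-driven score — so such permutations say nothing about the
  candidate's proximity to a *different* seed set. If they entered the
  null, no candidate could reach an empirical p below `k / n_mirna`
  (≈ 0.08 on the default synthetic network, destroying all power). They
  are excluded per candidate; the per-candidate `B` shrinks accordingly.
- **Degree-matched option.** `null_model="degree_matched"` draws each
  pseudo-seed from the ~10 miRNAs nearest in degree to one true seed,
  controlling for degree-driven score inflation. It remains non-default:
  on small networks the matched pool is dominated by the planted
  high-degree miRNAs themselves, which empirically makes the null
  anticonservative for background candidates.

BH adjustment is the standard step-up (via statsmodels); selection is
strict (`q < alpha`, default 0.05). Note that re-applying BH to an
already-adjusted vector is not a no-op in general — the only fixed points
of the step-up transform are constant vectors — so adjusted q-values must
never be fed back through the adjustment.

## Topology and hub calling

The candidate sub-network keeps the selected miRNAs, every gene adjacent
to at least one of them, and the induced edges. Centralities are computed
on the full bipartite sub-network (genes included), but ranking and hub
calling are restricted to the candidate miRNAs. Conventions: closeness is
the unnormalized `1/Σd` over reachable nodes (the magnitudes reported for
large miRNA–target sub-networks, ~4e-3, are consistent with this scale and
far below any normalized convention; a normalized variant is available);
betweenness is exact Brandes, undirected, unnormalized, endpoints
excluded. Ties at the k-th rank are all retained — an arbitrary drop among
tied nodes would make hub calls depend on label order. The hub set is the
intersection of the three top-k sets and may be empty.

## Enrichment

Over-representation uses the upper-tail hypergeometric test of the overlap
between a query gene set and each annotation term within a stated
universe, with BH adjustment. Terms are intersected with the universe
before testing; zero-overlap terms are retained at p = 1 by default so the
multiplicity correction sees the full term collection. Annotations are
read from GMT. The agreement of two result sets is summarized by both a
Jaccard rate and a reference-set rate (`|a∩b| / |a|`), since published
"overlap percentages" rarely state their denominator; the pipeline reports
the two side by side. No GO-graph ancestor propagation is attempted.

## Validation statistics

Fold changes follow `2^−ΔΔCt` with the calibrator defined as the mean ΔCt
of the control (resistant) group. Group comparison is Welch's two-sided
t-test on the ΔCt scale: ΔCt is the measurement-scale quantity with
approximately Gaussian noise, whereas fold changes are log-normal; the
scale choice is exposed to callers by operating on whichever vector they
pass. AUC uses the probabilistic pair-counting definition (ties count
half), identical to the scaled Mann–Whitney U; ROC points sweep the
observed thresholds.

## Synthetic data

The network generator emulates the structural assumption of the analysis:
trait-related miRNAs share target genes with the known seeds. Each of the
`n_seed` seeds deterministically targets a private block of 5 genes plus a
30-gene pool common to all seeds; each of `n_related` planted miRNAs hits
every seed-target gene independently with `shared_target_prob` (0.15
default) and every other gene with `background_prob` (0.01); background
miRNAs use `background_prob` everywhere. Defaults — 120 miRNAs, 400
genes, 10 seeds, 20 related — run the full pipeline in seconds. Setting
`shared_target_prob == background_prob` removes the planted signal
exactly (related and background rows become identically distributed),
which is the null condition used in the calibration tests; note that a
meaningful calibration network must plant *nothing*, including seed
blocks, because all candidate p-values share one observed seed draw and
any structural heterogeneity correlates them. Isolated nodes are
re-attached through one draw from their positive-probability pairs; nodes
with no positive-probability pair (e.g. background miRNAs at
`background_prob = 0`) stay isolated by design.

The fixture writer emits three pseudo-database tables that all contain the
true edge set plus source-specific decoy pairs (30% by default), so the
strict intersection recovers the planted network exactly; plus the seed
list, GMT annotations derived from the planted blocks with random decoy
terms, and a Ct table.

The expression generator draws per-sample ΔCt from
`Normal(μ0 − δ·1[case], σ²)` with a jittered constant reference Ct;
defaults δ = 1.5 cycles, σ = 1, n = 9 per group. The Gaussian shift
model yields the closed-form discrimination `AUC = Φ(δ/(σ√2)) ≈ 0.856`,
used as an oracle. What the generators do **not** emulate: correlated
targeting across database sources, expression-dependent detection limits,
plate effects, or amplification-efficiency variation — passing tests
demonstrate correctness of the algorithms under the stated model, not
performance on any real database release or patient cohort.

## Pipeline and reproducibility

`run_pipeline` executes network → RWR → significance → topology →
(optional) enrichment → (optional) validation, writing every intermediate
table plus a manifest with all parameters and SHA-256 checksums of every
output. The manifest carries no timestamps, so identical configuration and
seed give byte-identical outputs; the repeatability test diffs two runs.
All randomness flows from the single `rng_seed` (permutations) and the
generator configs' `rng_seed` (synthetic inputs).

At the default planted strength the pipeline's ranking is essentially
perfect (rank-AUC ≈ 1.0 for related vs background) but BH selection at
alpha = 0.05 typically selects nothing: with only ~110 candidates and a
permutation floor of `1/(B+1)`, the seed-resampling null is conservative
at this scale. The worked example therefore uses a strong-signal fixture
(`shared_target_prob = 0.5`), where selection recovers planted miRNAs
exclusively. On realistically sized networks (thousands of miRNAs) the
same machinery has far more resolution.

## Known limitations

- Binary edges only; prediction scores and support types in real database
  exports are ignored.
- The permutation null fixes topology; it does not model uncertainty in
  the network itself.
- Closeness/betweenness conventions matter when comparing with other
  tools; both normalized and unnormalized closeness are offered, but
  betweenness is unnormalized only.
- Empirical p-values are bounded below by `1/(B_eff+1)`; with the default
  1000 permutations, q-values below ~1e-3·m/k are unreachable.
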