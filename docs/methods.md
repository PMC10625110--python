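# Methods

## Differential expression and consistency integration

The built-in per-dataset test is deliberately lightweight: counts are
library-size normalized to CPM, log2(CPM + 1) transformed, and compared
between groups with Welch's two-sided t-test; log2FC is the difference of
group means on that scale and adjustment is Benjamini–Hochberg across all
genes. This is not a DESeq2 substitute — there is no dispersion shrinkage —
but the meta-integration rule, not the DE engine, is the substantive step,
and externally computed DE tables can be supplied instead
(`emtreg.io.read_de_table`).

The vote rule: with n tables and significance gate padj < α (default 0.05),
a gene is consensus-"up" when (datasets significantly up)/n ≥ f (default
f = 0.8) **and** no dataset calls it significantly down; symmetrically for
"down". Two choices the rule's verbal description leaves open are fixed
here: the denominator is always the number of supplied tables (a gene
absent from a dataset counts as non-support there — the strictest reading),
and any significant opposite call vetoes the gene ("consistently" read as
"without contradiction"). Both α and f are parameters. Consequences worth
knowing: the rule is monotone (raising f or lowering α never adds a gene)
and at f = 1.0 it reduces to the intersection of direction-consistent
significant calls.

## Maximal clique centrality

MCC(v) = Σ over maximal cliques C containing v of (|C| − 1)!. Maximal
cliques come from Bron–Kerbosch with pivoting (networkx `find_cliques`) with
a configurable cap (default 10⁶ cliques) that raises rather than running
unbounded. Isolated nodes count as singleton maximal cliques (0! = 1), so
every node has MCC ≥ 1 and the ranking is total; this edge case is a
package decision, since centrality tools differ silently here. Edge lists
from several interaction databases are merged into one simple undirected
graph (duplicate/reversed pairs merged, source tags accumulated, self-loops
dropped); ranking on the union is the default, per-source subgraphs can be
analysed by passing a single edge list. Ties share the minimum rank and
reports order ties lexicographically, so output is reproducible.

## Screen quantification

The migratory-distance statistic of a well at a timepoint is, by default,
the mean Euclidean distance of cells to their population centroid; the mean
pairwise inter-cell distance is available as `method="pairwise"`. The
underlying experimental statistic ("Euclidean distance between multivariate
centroids") is ambiguous between these readings, so both are provided and
neither is certified as the original instrument's definition.

Per replicate, logfc(t) = log2(d_treated(t) / mean control distance at t),
with distances floored at 10⁻⁶ µm (flagged) before the ratio; replicates are
averaged after the log transform. The AUC is the signed trapezoidal
integral of logfc over the 0–48 h grid at 4 h steps (exact for piecewise-
linear trajectories, hence the closed-form checks: constant 1 → 48,
linear 0→2 → 48).

Classification quantiles are linear-interpolation percentiles of each
(genotype, inducer) AUC panel, untreated controls excluded; the three rules
apply in order with first match winning, and the final label requires
agreement across inducers. The classification is invariant under adding a
constant to one genotype's whole panel (quantiles shift with the data) but
*not* under arbitrary monotone rescalings — percentile rules are
distribution-dependent by design. A degenerate panel (< 2 distinct AUCs per
genotype) is rejected.

Tumor volume uses the caliper formula 0.5·L·W² (mm³); if the recorded width
exceeds the length the values are swapped with a warning, so the result is
orientation-independent.

## Enrichment, semantic similarity, regulome

Enrichment is the classic one-sided hypergeometric upper-tail test per term
with BH across all tested terms; the elim/weight-style DAG decorrelation of
topGO-family tools is intentionally out of scope and the run manifest says
so. The universe defaults to the union of term member sets.

Term–term semantic similarity is the Wang graph-based measure on the is_a
DAG: S_t(t) = 1, each is_a hop toward the root multiplies by w = 0.8
(configurable), and sim(t₁,t₂) = Σ_{common ancestors}(S₁ + S₂)/(SV₁ + SV₂).
Term clustering is Ward hierarchical clustering on 1 − sim, cut at a given
k or at the best silhouette over k ∈ 2..10; between-cluster similarity is
reported as best-match-average. Note S_t(t) = 1 for the term itself, so for
a root R with single child A at w = 0.8, sim(A, R) = (0.8 + 1.0)/(1.8 + 1.0)
≈ 0.643 — the term's own S-value is never decayed.

The regulome network has one node per retained (FDR < α) enriched term per
query origin; similarity between nodes is the combined coefficient
k·Jaccard + (1−k)·overlap (k = 0.5) of their query∩term gene sets, with an
edge at ≥ 0.375 — the canonical enrichment-map pairing of coefficient and
cutoff, chosen because the cutoff value alone does not identify which
coefficient was used; pure Jaccard or overlap are available via `combine_k`.
Clusters are connected components above the cutoff (deterministic), labelled
by the most frequent non-stopword tokens of member term names; the stopword
list is bundled and affects labels only, never topology.

## Synthetic world

The generator states one fixed world per seed; all parameters below are
design choices, not tuning knobs.

- **Counts.** Gene-wise base means are log-normal (median 100, log-sd 1);
  counts are negative-binomial with shared dispersion α = 0.1
  (var = µ + αµ²). Defaults: 5 datasets, 6 samples/group, 1000 genes,
  100 planted DEGs at |log2FC| = 2 present in all datasets
  (consistency 1.0), plus 100 decoys planted in ⌈0.6·K⌉ datasets —
  decoys exist so the 80% vote has something to reject.
- **Interactome.** Each of 5 planted hubs sits in 3 node-disjoint 4-cliques
  built from consistently regulated genes (MCC = 3·3! = 18 by
  construction), over a sparse Erdős–Rényi background (mean degree 2) on
  200 other genes; disjoint cliques make the MCC ranking provably separable
  from degree. Edges are split at random across three source tags.
- **Screen.** Untreated scatter grows linearly, 20 µm + 2 µm/h·t. Planted
  inhibitors multiply the growth rate: suppression ×0.35 (in both genotypes
  for independent inhibitors, WT only for dependent inhibitors) or
  activation ×1.8 (KD only, dependent activators); 10 inhibitors per
  category among 188. Unplanted inhibitors get a per-inhibitor lognormal
  growth jitter (sd 0.15, shared across genotypes and inducers) so the AUC
  panel has the spread the quantile rules presuppose; planted inhibitors
  carry their exact effect so categories stay identifiable. Cells are drawn
  as an isotropic Gaussian cloud whose expected mean-distance-to-centroid
  equals the planted scatter, plus 5 µm positional noise. Replicates (3) and
  cells per well (50) were sized by a pre-hoc power calculation so AUC
  measurement noise (≈ ±1 log2·h) is well inside the null-jitter spread
  (≈ ±3 log2·h); they were not adjusted after observing test outcomes.
- **Terms.** 70 terms under 7 depth-1 branches of a rooted is_a DAG; each
  term is its branch's 20-gene core plus 10 unique genes, so within-branch
  overlap coefficient ≥ 2/3 and cross-branch sharing is 0. Branch 0's core
  is the first 20 planted DEGs, so enrichment of a recovered signature
  lights up one branch.

What the generator does **not** emulate: batch effects, library-size
heterogeneity, realistic GO depth or term-size distributions, cell division
or persistent cell tracks, and dose–response structure of inhibitors. A
green recovery test therefore establishes that the algorithms implement
their definitions and separate planted signal from the stated noise — not
that they would reproduce any particular published gene list from real data,
which depends on external databases and datasets outside this package.

## Numerical conventions

Percentiles use linear interpolation between closest ranks. BH adjustment
is the statsmodels step-up implementation with monotonicity enforcement,
shared by the DE and enrichment layers. Distances below 10⁻⁶ µm are floored
before log ratios and flagged. Untestable genes (zero variance in both
groups) receive p = 1 rather than NaN. All randomness flows from
`GeneratorConfig.seed` through named substreams, so every output file is
byte-identical across runs with the same seed.
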