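# Methods

## The proximity model

The package treats a remedy ingredient as a set *A* of protein targets and
a disease as a key gene set *B*, both embedded in an undirected background
PPI network. Distances d(a, b) are unweighted shortest-path hop counts;
edge confidence scores (STRING's 0–1000 "combined score", auto-detected and
rescaled to [0, 1]) are used only to threshold edges at read time, never as
weights. Three set distances summarise the A–B relationship: the all-pairs
mean ⟨d_AB^S⟩, the closest-member mean ⟨d_AB^C⟩ (each node contributes its
distance to the nearest member of the opposite set, averaged over ‖A‖+‖B‖
terms), and the kernel distance ⟨d_AB^K⟩, a log-sum-exp soft minimum in
which each pair contributes e^{−(d+1)}. The kernel exponent grouping —
the +1 inside the exponent, the 1/‖B‖ (resp. 1/‖A‖) inside the logarithm —
is the standard kernel set distance of the network-medicine literature;
it is the only parse under which the kernel distance exceeds the mean
distance on every row of the packaged reference table, as it must
(−ln of a mean of terms each ≤ e^{−(d_min+1)} is ≥ d_min + 1).

The interference call is the separation score

    S_AB = ⟨d_AB^S⟩ − (⟨d_AA^S⟩ + ⟨d_BB^S⟩)/2,

with ⟨d_AA^S⟩ computed by the same all-pairs formula with both arguments
equal, so self-pairs (d = 0) are included. The alternative
nearest-other-member convention is available (`within_set="nearest"`;
singleton sets are defined to have within-distance 0 under it). The call is
strict: S_AB < 0 interferes; S_AB = 0 (e.g. A = B) does not. Exported
tables round to 2 decimals; full precision is kept internally.

A consequence worth knowing when interpreting S_AB: under the
self-pair-inclusive convention, if all pairwise distances were equal the
score would be m(‖A‖+‖B‖−2·overlap)/(2‖A‖‖B‖) ≥ 0 — a small positive bias.
Negative scores therefore require genuine geometric structure: cross-set
distances systematically shorter than within-set distances, as when an
ingredient's targets each directly contact many members of a dispersed key
set. Merely sampling targets near one key gene does not produce S_AB < 0.

**Unreachable pairs** are dropped from every mean, with the dropped count
recorded per ingredient, rather than imputed at an arbitrary constant; the
default pipeline restricts the background to its largest connected
component, where the issue is rare. Whether to restrict to one component is
a pipeline default, not a claim about how any particular study handled it.
A node unreachable from an entire opposite set makes the kernel distance's
inner sum zero and is reported as an error naming the node.

## Hub scoring

Maximal clique centrality: MCC(v) = Σ (|C|−1)! over maximal cliques C
containing v, enumerated by Bron–Kerbosch with pivoting. An isolated node
owns its singleton maximal clique and scores 0! = 1, keeping every node
scored. Selection of the top-k core set includes all nodes tied with the
k-th score (logged), so results do not depend on hidden orderings. k
defaults to 25 but is a parameter: the size of a "much higher scores" core
is a judgement call, not a constant.

## Stand-in statistical stages

*Differential expression* uses a per-gene Welch two-sample t statistic with
BH adjustment rather than a moderated (empirical-Bayes) t: what downstream
stages consume is the threshold contract — |log2FC| > 1.0 (strict) and
q < 0.05 — and at the benchmark's effect sizes and sample sizes variance
shrinkage changes nothing material. Matrices are assumed log2-scale; a
loud warning fires when values exceed 50. Genes with zero variance in both
groups get p = 1 and a flag.

*Coexpression modules*: unsigned adjacency |cor|^β (sign choice is an open
convention; unsigned is the common default), TOM smoothing, average-linkage
clustering of 1 − TOM. Two cut parameters matter and play different roles:

- `branch_cut` (default 0.97) separates coexpression branches from the
  unclustered background near the top of the dendrogram. Genuine modules
  join far below it (a block with within-correlation r at power β joins
  near 1 − r^β·(adjusted for TOM); ≈ 0.74 for r = 0.8, β = 8), while
  uncorrelated genes join near 1.
- `cut_height` (default 0.25) is the module-merge height: detected modules
  whose eigengenes are nearly collinear (1 − cor < 0.25) are merged. A flat
  tree cut at 0.25 would instead demand within-module TOM similarity above
  0.75, which only near-perfectly correlated blocks attain — that reading
  makes the parameter vacuous on real data, so it is not used.

Clusters below `min_module_size` (default 50) are relabelled grey.
Module labels are size-ranked strings (module1, module2, …); a color alias
table is emitted for familiarity with the conventional palette. The module
eigengene is the first right-singular vector of the standardized module
submatrix, sign-fixed against the module's mean profile; its Pearson
correlation with the 0/1 phenotype (with the usual t-transform p) gives the
module–trait table. The soft threshold is the smallest candidate power
whose scale-free fit R² (regression of log10 p(k) on log10 k over ≥5
occupied equal-width degree bins, slope required negative) reaches 0.85,
falling back to the argmax with a warning.

*Over-representation* is the hypergeometric upper tail P(X ≥ k) with BH
across terms; selection requires p < 0.05 and q < 0.05. The universe
defaults to all genes in the collection plus the query, since published
backgrounds are rarely stated; q is BH (the common default for "q-value"
in this setting).

*Survival screening* stratifies each gene at the median (ties to the low
group — an explicit rule so results are deterministic), compares strata
with the standard two-group log-rank test (lifelines), and calls genes at
p < 0.05 without multiple-testing correction by default, mirroring the
plain per-gene screen convention; BH is available via `adjust="bh"`.

## Synthetic data

All generators hang off one `SynthConfig`; a single global seed fans out to
fixed per-component child seeds so regenerating one input never perturbs
the others, and identical configs give byte-identical files.

- **Background network**: preferential attachment from an initial
  (m+1)-clique; each new node attaches to m distinct existing nodes drawn
  proportionally to degree, giving C(m+1,2) + m(n−m−1) edges, a connected
  graph and a heavy-tailed degree law. Defaults n = 2,000, m = 2 — a
  desk-scale stand-in for a genome-wide interactome (~10× smaller, same
  degree law, smaller diameter).
- **Disease context** (`gen_disease_network`): the 10 last-added
  (peripheral) nodes form the key set, and all of them are wired to a
  common pool of 40 interactor nodes. This emulates a disease protein
  complex with shared binding partners and creates the geometry described
  above in which S_AB < 0 is attainable: anchor nodes are one hop from
  every key gene while the key genes (and the anchor nodes) remain
  mutually distant.
- **Expression**: N(8, 1) log2 baselines; 50 planted DE genes shifted by
  2 log2 units in the disease group (40 vs 40 samples); two planted
  60-gene modules driven by latent factors with within-block correlation
  0.8, the first module's factor shifted by 2 in the disease group (the
  trait link). A separate generator (`gen_coexpression`) produces
  power-law-sized correlated clusters — sizes drawn from a
  preferential-attachment degree sequence — for benchmarks that need a
  heavy-tailed connectivity distribution (the scale-free fit crosses
  R² = 0.85 at power 4 on the frozen benchmark seed).
- **Survival**: exponential event times at rate λ·HR^z (λ = 1/1000 per
  day, z the standardized expression of the designated prognostic gene),
  independent exponential censoring tuned so ≈30% of subjects are censored.
- **Targets**: active ingredients draw uniformly from nodes within 1 hop
  of the key set, inactive ones from the whole network; 20 ingredients of
  10 targets, half active.

What the generators do **not** emulate: realistic transcriptome marginals
(library-size effects, count noise, batch structure), PPI motif structure
beyond the degree law, study-specific confounding, or correlated censoring.
Passing benchmarks therefore demonstrate that each stage recovers the
signal it is designed for under its stated model — not that the pipeline's
biological conclusions on any real cohort are correct.

## Benchmark problem sizes

Recovery benchmarks run at: 2,000 genes × 80–100 samples (differential
expression, modules), 200 subjects × 100 replicates (survival power at
hazard ratio 3), 2,000-node network × 20 ingredients (proximity
classification), brute-force cross-checks on graphs of ≤ 12 nodes, and
score invariants on 1,000 random set pairs. These sizes give each stage
comfortable statistical power while keeping a full run of the suite and
the acceptance script to a few minutes on one CPU.

## Packaged reference tables

The three case-study tables (36-ingredient ADMET, 105 predicted targets,
17 published proximity rows) are consumed as *inputs*: the published
proximity values were computed on a proprietary merged background network
(16,677 proteins, 243,603 interactions from 15 source databases) that is
not recoverable from the publication, so those rows are validated for
internal consistency (d_C ≤ d_S, d_K > d_S, the S < 0 refilter) rather
than recomputed. Loaders validate row counts and ranges on every load.

## Known limitations

- The flat two-stage cut is a static simplification of dynamic hybrid tree
  cutting; modules whose dendrogram branches exceed `branch_cut` (very weak
  correlation) are missed.
- Clique enumeration is exponential in the worst case; the node cap
  (default 10,000) forces the caller to restrict to a component or raise
  it knowingly.
- The separation score inherits the positive bias of self-pair-inclusive
  within-set means; comparisons should be within one background network,
  not across networks of different density.
- Degree-preserving randomization z-scores for proximity are out of scope.
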