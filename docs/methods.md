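# Methods

This note records the models implemented in `xtalkflow`, the defaults and
why they were chosen, what the synthetic benchmark does and does not
emulate, and the numerical decisions a maintainer would want spelled out.

## Pipeline model

### Preprocessing

Clusters with fewer than 20 cells are removed, then genes detected in
fewer than 5% of the remaining cells ("fewer than" strict in both rules).
Normalization is counts-per-10,000 followed by `log1p`; scaling is a
per-gene z-score clipped at ±10 (clipping guards the forest and network
stages against single-cell outliers).  Both layers are kept: the
non-negative normalized layer feeds every formula that presumes
non-negative expression (communication strength, ACS products, ACI, rank
correlations — ranks are invariant to the per-gene monotone scaling, so
normalized and scaled layers give identical Spearman values), while the
scaled layer provides node features for representation learning (below).
Optional per-cell QC flags (top-1% totals, mitochondrial fraction > 0.2)
exist but are off by default.  Target genes per receiver cluster are
either user-supplied (authoritative when given) or the receiver's
over-expressed genes by one-vs-rest Wilcoxon rank-sum,
Benjamini–Hochberg-adjusted p < 0.05 and log fold-change > 0.25 on the
normalized layer, the standard single-cell default; the DEG choice only
selects the target roster.

### Communication scoring

The mass-action Hill strength uses cluster means on the normalized layer;
multi-subunit complexes enter through the geometric mean of subunit
cluster means, so one absent subunit zeroes the complex.  Agonist and
antagonist terms use per-cluster arithmetic means in sender and receiver
separately (the pooled alternative is ambiguous; per-cluster keeps the
factors interpretable as local modulation) and reduce to exactly 1 when
the gene lists are empty.  `K_h = 0.5`.  Significance is a label
permutation test with 100 permutations by default; the p-value counts
permuted strengths `≥` the observed one — ties inclusive — so a degenerate
matrix yields p = 1, never 0.  Pairs with p > 0.1 are discarded;
per-receptor strengths are summed over retained pairs and all senders,
and receptors reaching 10% of the maximum total become signal nodes.

### Prior hypergraph

`S_H = |PPR(signal → SSC) × ρ(SSC, target)|` with personalized PageRank
(damping 0.85, the canonical default; dangling mass returns to the seed;
directed edges, absolute weights) on the union receptor→TF graph, and
Spearman over receiver cells.  A multi-subunit signal absent from the
prior graph is seeded per subunit and averaged.  Triples with `S_H = 0`
are dropped.  Binarization keeps exactly `ceil(0.10 · N)` triples; ties at
the threshold are resolved lexicographically by (Signal, SSC, Target) and
truncated — an arbitrary but deterministic rule that makes runs
reproducible.  Fewer than 10 scored triples promote everything (with a
warning) rather than producing an empty hypergraph.

Training samples: positives are the hyperedges; an equal number of
negatives is drawn half from the lowest-`S_H` scored triples (hard
negatives) and half from role-respecting random triples outside the
scored set (easy negatives).  The 50/50 mix balances the two negative
flavours in the absence of a principled ratio.  The train/validation split
is a seeded, class-balanced 80/20 partition.

### Representation learning

Two hypergraph convolutions `Z' = ELU(D_v⁻¹ H D_e⁻¹ Hᵀ Z Θ)` — mean
aggregation node→hyperedge→node.  An alternative form with `D_e`
un-inverted (sum aggregation scaled by edge degree) is available as
`raw_de=True`; the normalized form is the default because the
un-normalized product is dimensionally a tripled sum for 3-uniform
hypergraphs and destabilizes training.  Zero-degree nodes pass their
transformed features through unchanged so genes outside every hyperedge
still receive embeddings.  Role heads are independent two-layer MLPs
(ELU inner, ReLU outer); layer sizes are input → 128 → 64 for the trunk
and 64 → 32 → 16 for the heads — small enough to train on hundreds of
samples, large enough not to bottleneck the ~200-gene problems this
package targets.  All parameters use seeded Glorot-uniform initialization.

Node features are each gene's **scaled** expression across receiver cells
(subsampled to at most 2,000 cells to bound the first-layer width).  This
is a deliberate choice: the raw-normalized rows are strictly non-negative
and dominated by shared library-size structure, which makes the initial
role-head outputs nearly collinear and parks the cosine-product activity
score at its uninformative `PA ≈ 0.5` saddle for many epochs; z-scored
features spread the initial cosines so the loss descends immediately, and
in the synthetic benchmark they improve held-out AUROC from ≈ 0.79 to
≈ 0.88 at the 80/20 split while converging several times faster.

`PA = |cos(y_s, y_c) · cos(y_c, y_t)|`, defined as 0 when any embedding
has zero norm.  The loss is binary cross-entropy with PA clamped to
`[1e-7, 1 − 1e-7]`, reduced as the batch mean (a constant rescaling of the
summed form absorbed into the learning rate).  Adam (lr 1e-3, batch 128,
up to 200 epochs) with exponential decay γ = 0.97 per epoch and early
stopping after 20 epochs without validation improvement; the
best-validation parameters are returned.  Gradients, including the cosine
and hypergraph-convolution terms, are computed analytically and verified
against central finite differences in the test suite.  With a fixed seed
training is bit-reproducible.  Pathways with PA strictly above 0.75 are
activated.

### Regulatory strength and selectivity

For every activated (SSC, target) pair the per-cell activation strength
`ACS = x_SSC · x_target` (normalized layer, hence non-negative) is
regressed on the expression of exactly the signals whose activated
pathways share that pair.  The regressor is a Random Forest (500 trees,
sqrt-features per split, unrestricted depth — library-standard defaults);
PRS is the mean decrease in R² over 10 seeded feature permutations,
floored at zero.  Multi-subunit signal expression is the per-cell
geometric mean of subunit normalized values.  A constant ACS yields
all-zero PRS with a warning.  Fewer than 30 cells triggers a warning
rather than an error; the regression is then fragile.

Fidelity and specificity are PRS shares within the Target- and
Signal-crosstalk modules, so each sums to 1 per module whenever the
module's PRS sum is positive; zero-sum modules report missing values and
are excluded from summaries with a logged count.  TRS sums PRS over SSC
routes of a signal-target pair, and the total fidelity/specificity
normalize TRS per target and per signal respectively.  Compound modules
(shared signal+SSC or SSC+target) use the same normalization.  The
activation index is `ACI = xy/(K_h + xy)` per cell with `K_h = 0.5`.

Receiver subclustering takes the signal's top-10 targets by total
specificity as markers, weights each marker proportionally to its
specificity (weights normalized to sum 1), and runs k = 2 k-means on
marker expression scaled by `sqrt(weight)` — algebraically the weighted
squared-error objective.  The cluster with the higher weighted mean marker
expression is labelled "interacted", on the rationale that
high-specificity targets are the signal's response markers.

## Synthetic benchmark

The generator emulates the structure of a receptor→TF→target cascade, not
any particular organism: roles split 1:4:15 (200 genes by default → 10
receptors, 40 TFs, 150 targets; remainders go to targets), Bernoulli
edges with densities 0.2 (receptor→TF) and 0.1 (TF→target), signed
strengths uniform on (0.5, 2.0), and a resampling guarantee that no TF or
target is orphaned.  Ground-truth pathways are exactly the composable
edge pairs.

Expression follows Euler–Maruyama integration of
`dx = (prod(x) − x) dt + 0.3 · sqrt(prod + x) dW` (decay 1, dt 0.05,
200 steps ≈ 10 relaxation times, trajectories clipped at 0), where a
regulated gene's production is `0.1 + 2 · u²/(1 + u²)` of the positive
part of the weighted regulator sum, and receptors have cluster-specific
basal rates drawn from Uniform(0.2, 2.0) — 1,500 cells in 3 equal
clusters by default.  Stationary states become Poisson counts (rate 10
per expression unit), then technical noise: per-gene log-normal outlier
amplification (probability 0.01, σ = 1) and per-entry Bernoulli dropout
(probability 0.3).  The dropout default was sensitivity-checked rather
than fitted.  Optionally the simulator appends one ligand gene per
receptor, expressed in the two sender clusters, plus the matching
ligand-receptor table, so the communication stage can run end to end on
synthetic data.

What the simulator does **not** emulate: master-regulator differentiation
profiles, pseudotime trajectories, batch effects, doublets, or realistic
mRNA capture statistics.  Passing benchmarks therefore demonstrates that
the pipeline recovers planted compositional structure under Poisson +
dropout noise — not performance on any real tissue.

The recovery benchmark builds the hypergraph skeleton from the training
positives, trains on a class-balanced labelled split (an internal 80/20
class-balanced partition of the training set drives early stopping),
scores held-out triples by PA, and reports AUROC and AUPRC.  Under the
defaults the 80/20 split reaches AUROC ≈ 0.88, and training on only 20%
of the samples still averages ≈ 0.72 over five seeds — comfortably above
the 0.6 working floor for the low-supervision regime.  A
`pairwise_score_product` adapter (|signal-TF| × |TF-target|) lets any
pairwise edge scorer be evaluated in the same harness.

## Shared-TF evaluation utilities

Coverage is `|A ∩ B| / |B|`.  Association between predicted and reference
TF lists uses the standard two-sided Fisher exact test (sum of
hypergeometric masses of tables no more probable than the observed one);
the single-table hypergeometric mass is separately exposed as
`point_probability`.  The chi-square test is Pearson's without continuity
correction, 1 df, undefined on zero margins.  The contingency builder
follows `a = |A∩B|`, `a+b = |A|`, `a+c = |B|`, `a+b+c+d = n` with the
universe size a caller decision (default: the union).  The low-expression
co-expression filter on reference TFs has no canonical threshold and is
left to the caller.

## Determinism and problem sizes

Every stochastic step draws from a generator derived from
`RunConfig.seed` via stable per-stage seed sequences; two runs with equal
inputs and configuration produce byte-identical pathway tables (enforced
by a test).  Output floats are serialized with six significant digits so
re-runs diff cleanly.  The test suite exercises the full default-scale
benchmark (200 genes, 1,500 cells) for the recovery criteria and a
60-gene, 240-cell configuration for end-to-end pipeline and CLI tests —
sizes chosen so the whole suite runs in a few minutes on one CPU.

## Known limitations

- Hyperedges are strictly 3-uniform; longer regulatory chains
  (receptor→TF→TF→target) are out of scope.
- The permutation importance underlying PRS is shared-variance-blind:
  strongly correlated signals split importance, deflating both pathways'
  PRS.  Fidelity/specificity inherit this.
- The CCC stage has no spatial awareness; all non-receiver clusters are
  senders by default.
- `PA`'s absolute value means anti-aligned embeddings score as activated;
  this mirrors the sign-blind prior score but makes PA unsuitable for
  inferring regulation sign.
- The DEG-based target selection is a roster heuristic, not an effect
  estimate; explicit target lists override it entirely.
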