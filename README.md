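# xtalkflow

Crosstalk-aware inference of intracellular regulatory pathways activated by
cell-cell communication, from single-cell RNA-seq.

When a receiver cell cluster receives ligand signals from its neighbours,
each activated receptor relays information through transcription factors
(TFs) to downstream target genes.  Different receptors often route through
the *same* TFs — the pathways cross-talk — so asking "which receptor drives
this target, and through which TF?" requires reasoning about ordered
triples (signal, SSC, target), where the SSC (shared signaling component)
is a TF potentially shared by several pathways.  `xtalkflow` models each
candidate triple as a hyperedge of a 3-uniform hypergraph and estimates:

- **communication strength** of each ligand-receptor pair between clusters
  with a mass-action Hill model,
  `P = LR/(K_h + LR) · (1 + AG_s/(K_h+AG_s)) · (1 + AG_r/(K_h+AG_r)) ·
  K_h/(K_h+AN_s) · K_h/(K_h+AN_r) · n_s n_r / n²`,
  with a label-permutation significance test;
- a **prior hyperedge score** `S_H = |PPR(signal → SSC) · ρ(SSC, target)|`
  combining personalized PageRank on the receptor→TF prior network with
  Spearman correlation over receiver cells; the top 10% of triples become
  the prior hypergraph;
- **pathway activity** `PA = |cos(y_s, y_c) · cos(y_c, y_t)| ∈ [0, 1]` from
  node embeddings learned by two hypergraph convolution layers
  (`Z' = ELU(D_v⁻¹ H D_e⁻¹ Hᵀ Z Θ)`) plus per-role two-layer MLP heads,
  trained with binary cross-entropy (Adam, exponential LR decay);
  pathways with PA > 0.75 are called activated;
- **pathway regulatory strength (PRS)**: Random-Forest permutation
  importance of each signal when regressing the per-cell activation
  strength `ACS = x_SSC · x_target` on the signal expressions;
- **fidelity** (a pathway's PRS share within all pathways ending at its
  target) and **specificity** (its share within all pathways leaving its
  signal), plus signal-target totals (TRS) and compound-module variants,
  a per-cell activation index `ACI = xy/(K_h + xy)`, and a weighted
  k-means subclustering of receiver cells by high-specificity targets.

A built-in simulator generates ground-truthed benchmarks: a random 3-layer
regulatory network (receptors : TFs : targets = 1 : 4 : 15), chemical-
Langevin expression dynamics, Poisson counts with dropout/outlier noise,
and the composable receptor→TF→target pairs as truth, scored by
AUROC/AUPRC.

The package is aimed at computational biologists analysing cell-cell
communication who want receptor-resolved, TF-resolved target regulation
rather than flat ligand-target links.

## Worked example

The synthetic route exercises every stage without external data:

```python
from xtalkflow import CrosstalkModel, RunConfig
from xtalkflow.io import LRDatabase, LRRecord, PriorNetworks
from xtalkflow import simulate as sim

grn = sim.generate_grn(n_genes=60, seed=0)
ds = sim.simulate_expression(grn, n_cells=240, seed=1, with_ligands=True)
model = CrosstalkModel(
    expr=ds.to_expression_data(),
    lr_db=LRDatabase([LRRecord([ds.ligand_of[r]], [r]) for r in grn.receptors]),
    priors=PriorNetworks(grn.receptor_tf_edges, grn.tf_target_edges),
    receiver="C1", user_targets=list(grn.targets),
    config=RunConfig(seed=0, epochs=40, patience=10, n_permutations=50))
results = model.fit()
print(results.summary())
```

prints

```
Crosstalk pathway inference results
===========================================
receiver cluster:        C1
signals (receptors):     3
scored triples:          630
hyperedges (prior):      63
activated (PA > 0.75):  70
best validation loss:    0.3793 (epoch 13)

Top pathways by PRS:
Signal      SSC         Target            PA       PRS     Fid     Spe
R3          TF6         T33            0.793    1.3835   0.563   0.050
R3          TF6         T36            0.752    1.3233   0.385   0.048
...
```

Reading: all three simulated receptors pass the communication filter; 630
(signal, SSC, target) triples score positively; the 70 with learned
activity above 0.75 are the activated pathways.  The top row says target
T33 receives 56% of its incoming regulation (fidelity 0.563) through the
R3→TF6 route, while T33 accounts for only 5% of R3's outgoing regulation
(specificity 0.050) — R3 fans out over many targets.  The same objects are
available from the command line (`xtalkflow run`, with per-stage
subcommands `ccc`, `hypergraph`, `train`, `prs`, `metrics`, `simulate`,
`benchmark`); `results.save(dir)` / `xtalkflow run --out dir` write the
pathway table and signal-target totals as TSV.

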