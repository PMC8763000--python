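# somcell

Self-organizing-map expression portraits, spot modules, cell-state
diversity and RNA velocity for single-cell transcriptomics — a pipeline
for studies that track how treatment reshapes a population of cells,
e.g. tumor cells developing drug resistance across several therapy
conditions.

## What it computes

**SOM portraits.** A Kohonen network is trained on *gene* profiles
(each training vector is one gene's centralized log expression across
all cells), so co-expressed genes map to nearby units of a rectangular
grid (60×60 by default, K = 3,600 "metagenes").  Evaluating all K
prototype profiles at one cell's coordinate gives that cell's
**portrait** — a grid image of over- and under-expressed metagenes.

**Spot modules.** Connected regions of a portrait above its 90%
expression quantile are segmented into labeled spots; a spot's member
genes form a co-regulated module whose per-cell mean expression profiles
the module's activity.

**Transcriptional states and diversity.** Cells cluster on their
portraits (correlation distance, average linkage, silhouette-selected
k); state × treatment-group composition tables quantify the
redistribution of cells, and its Shannon entropy H = −Σ p ln p is the
alpha diversity of each group's state repertoire.

**RNA velocity.** Under the steady-state model, unspliced and spliced
abundance satisfy u = γ·s at equilibrium; the per-gene ratio γ is fit by
zero-intercept regression on extreme-quantile cells of kNN-pooled
layers, and the residual v = u − γ·s is the expression change under way.
Velocities aggregate into metagene space (which regions of the portrait
are switching on or off, per treatment group) and project onto any 2-D
cell embedding as a vector field whose sources and sinks mark transient
and stable states.

A first-class synthetic-data generator (`somcell.syndata`) emulates the
assumed study design — unequal treatment groups, latent expression
programs with group-dependent mixing, negative-binomial counts, and
spliced/unspliced layers with planted steady-state ratios and source
states — so every stage is testable against known ground truth.

## Worked example

```python
import numpy as np
import somcell

cfg = somcell.SimConfig(
    n_groups=2, group_sizes=(120, 180), group_names=("S", "R"),
    n_programs=3, genes_per_program=(40, 60), n_background_genes=100,
    program_mixing=((0.70, 0.25, 0.05), (0.10, 0.30, 0.60)),
    velocity_source_states=(2,), seed=0,
)
ds = somcell.simulate(cfg)
matrix = somcell.log_centralize(ds.to_expression_matrix())
model = somcell.train_som(matrix, somcell.SOMConfig(grid_rows=20, grid_cols=20,
                                                    epochs=30, seed=1))
print(f"{model.n_units} metagenes; quantization error "
      f"{model.qe_initial:.1f} -> {model.qe_final:.1f}")

assign = somcell.cluster_portraits(model, k="auto", k_range=(2, 8))
print(f"states selected: k = {assign.k}")

table = somcell.composition(assign, ds.cell_groups)
print(table.counts)
div = somcell.diversity(table)
print("alpha diversity per group:",
      {g: round(h, 3) for g, h in div.per_group.items()})

atlas = somcell.detect_spots(assign.centroids["C1"], model, threshold=0.90)
print(f"spots in C1 portrait: {[(s.label, s.n_genes) for s in atlas.spots]}")

vm = somcell.estimate_velocity(ds.spliced, ds.unspliced, ds.gene_ids,
                               n_neighbors=30, seed=0)
src_field = somcell.metagene_velocity(
    vm, model, cells=np.flatnonzero(ds.true_program == 2))
print(f"max metagene velocity in source cells: {src_field['all'].max():.2f}")
```

Output:

```
400 metagenes; quantization error 137.9 -> 51.3
states selected: k = 3
group    R   S
state
C1     110   7
C2      22  81
C3      48  32
alpha diversity per group: {'R': 0.91, 'S': 0.784}
spots in C1 portrait: [('A', 42)]
max metagene velocity in source cells: 8.08
```

Reading it: training reduced the quantization error (the map fits the
gene profiles); silhouette selection recovered the three planted
programs as states C1–C3; the composition table shows C1 is almost
exclusive to the resistant group R while C2 is sensitive-dominated, and
R spreads over more states than S — hence its higher alpha diversity
(0.91 vs 0.78 nats).  The C1 mean portrait contains one overexpression
spot whose 42 genes recover the planted program, and the metagene
velocity field of the designated source state is strongly positive at
that program's grid region: its expression is still rising.

Disk-based inputs work the same way: `somcell.read_matrix(dir, meta)`
reads 10x-style MTX triplets (or a dense TSV) with a metadata table, and
`somcell.write_dataset(ds, dir)` writes a synthetic dataset in exactly
those formats, plus spliced/unspliced layers and the planted gene sets
as GMT.

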