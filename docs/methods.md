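# Methods

`somcell` implements a self-organizing-map (SOM) "portrait" analysis of
single-cell RNA-seq for studies of developing drug resistance, together
with steady-state RNA velocity projected into both cell space and
metagene space.  This note documents the models, the defaults and why
they were chosen, the numerical decisions, and what the synthetic data
do and do not establish.

## Preprocessing

Inputs are UMI count matrices (10x-style MatrixMarket triplets or dense
TSV) with a cell-metadata table carrying a treatment-group label.
Quality control uses generic count filters (genes detected in ≥ 3 cells,
cells with ≥ 200 detected genes, both configurable); no doublet or
ambient-RNA modeling is attempted.  Expression is transformed as
`log(1 + x)` and centralized gene-wise (every gene has zero mean across
cells), the representation the SOM trains on.  Because subsetting cells
breaks exact zero means, `centralize` can be re-applied after any
selection step; it is idempotent.

Treatment groups are equalized by seeded random subsampling to a fixed
target (default 2,000 cells per condition) so that no condition
dominates the map.  A further stratified thinning step preserves
heterogeneity while shrinking the data: cells are clustered into
communities of a kNN graph (15 neighbors on the top 30 principal
components; Leiden with the resolution parameter tuned by bisection
toward 27 communities, any count within ±20% accepted), and
`round(0.20 × size)` cells (round half up, floor 1) are drawn without
replacement from every community × treatment-group block.  The stratum
count is a goal, not a contract: it is data-dependent, and it only needs
to exceed the number of conditions and of intrinsic cell states.
Precomputed stratum labels can be supplied instead, in which case the
draw is exact per block.

## Gene-space SOM and portraits

The SOM is trained on gene profiles: each training vector is one gene's
centralized log expression across all cells, so the map has dimension
`n_cells` and K = grid_rows × grid_cols prototype profiles ("metagenes",
60 × 60 = 3,600 by default).  Co-expressed genes map to nearby units.  A
cell's portrait is the grid-shaped slice of all K codebook values at
that cell's coordinate.

Training is classic online Kohonen learning, sequential by construction:

- presentation order reshuffled every epoch (seeded);
- best-matching unit (BMU) by Euclidean distance, ties to the lowest
  unit index;
- neighborhood: Gaussian of width r/2 hard-truncated at grid distance
  r, with the radius r decaying exponentially from half the larger grid
  dimension (30 for the default grid) to 1 across epochs;
- learning rate decaying exponentially 0.1 → 0.01;
- 20 epochs by default.  With sample-mean initialization (below) the
  map's topology and the downstream portraits stabilize well within 20
  passes at the gene counts this package targets (hundreds to a few
  thousand); the epoch count, schedules and grid are all configurable.

Initialization ("seeded-random") sets every prototype to the mean of 32
randomly drawn gene profiles.  This keeps the codebook inside the
centered data subspace, with two exact consequences: the portrait
averaged over all cells is the zero portrait (gene-wise centralization
transfers to every linear combination), and duplicated cells yield
bitwise-identical portrait columns.  A PCA-plane initialization is
available for faster topology formation.

The inner loop is a compiled (numba) kernel: BMU scoring runs against a
float32 shadow of the codebook (the distance ranking is insensitive to
float32 rounding), while the float64 master codebook accumulates the
updates, preserving the exactness properties above to ~1e-13.  Identical
seed and input give identical results within a machine.  The
quantization-error trace records the mean squared gene-to-BMU distance
per epoch at presentation time; exact values before and after training
(`qe_initial`, `qe_final`) are computed separately, and training must
not increase the exact error.

## Supporting maps, spots, states

The variance map is the per-unit variance of the codebook profile across
cells.  The overexpression summary map thresholds each group portrait at
its own 90% quantile (per-portrait thresholds, since portraits differ in
scale) and takes the per-unit maximum across groups.  Region correlation
is the Pearson correlation between region-mean codebook profiles; a
zero-variance region yields NaN rather than an error.  Difference
portraits are elementwise subtractions (e.g. each resistant condition
minus the sensitive one).

Spot modules are segmented from a portrait by marking units strictly
above the portrait's 90% quantile (strictness makes a constant portrait
yield no spots), taking 8-connected components, discarding components
with fewer than 4 units, and labeling A, B, C, … by decreasing total
portrait mass.  A spot's genes are the union of its units' BMU member
lists; spots within one atlas are unit-disjoint by construction.
Atlases from several portraits merge by fusing spots whose unit overlap
exceeds Jaccard 0.25 (transitively); residual sub-cutoff overlaps are
resolved in favor of the more massive spot, and a merged spot's mass is
the maximum over its constituents (masses from different portraits are
not additive).  Spot profiles are per-cell means of the member genes'
centralized log expression.

Cells are clustered into transcriptional states on their flattened
portraits using correlation distance with average-linkage agglomeration
(deterministic); the state count is fixed or chosen by the silhouette
maximum over k = 2..12 (ties to the smaller k), with a seeded k-means
fallback.  States are labeled C1, C2, … by decreasing size.  State ×
group composition tables carry row and column fractions, and alpha
diversity is the Shannon entropy −Σ p ln p of a composition vector
(natural log; 0 for a one-state group, ln k for a uniform spread over k
states).  Gene-set signatures score as the unweighted per-cell mean of
the member genes' centralized log expression (absent genes dropped with
a warning), and group differences are tested by one-way ANOVA with
Tukey's HSD post hoc at α = 0.05.

## RNA velocity

The steady-state model posits `u = γ s` per gene at transcriptional
equilibrium; velocity is the residual `v = u − γ s`.  Spliced and
unspliced layers are first smoothed by kNN pooling (mean over each
cell's 30 nearest neighbors in the top-30-PC space of log1p spliced
counts; pooling preserves exact per-gene proportionality, so data at
steady state remain exactly at steady state).  γ is then the slope of a
zero-intercept regression of u on s over the cells in the extreme 5%
tails.  Extremeness is judged on the combined max-normalized signal
`s/max(s) + u/max(u)` rather than on s alone: the count noise of the two
layers is independent, so the combined criterion anchors the tails to
genuinely induced or silent cells; tails of the noisy regressor alone
select its own noise excursions and attenuate the slope (measured
median error 6–16% versus ~4% on synthetic kinetics).  Genes with fewer
than 10 usable tail cells or no spliced signal are flagged unfit; their
velocity columns are zeroed and excluded from every aggregation.

Metagene velocity assigns each SOM unit the mean velocity of its member
genes over the selected cells — the mean, not the sum, so units with
different gene counts stay comparable — with one field per treatment
group when groups are supplied; units without fitted members are 0.

The embedding projection follows the standard construction: each cell's
velocity vector is Pearson-correlated with the expression displacement
to its k = 30 nearest embedding neighbors, and the unit directions
toward the neighbors are averaged with softmax(corr / 0.05) weights,
minus the unweighted mean direction — so zero velocity maps to an
exactly zero vector, and the field is equivariant under rotations of
the embedding.  Velocities are centered per gene across cells before
the projection (switchable): when a population is systematically off
steady state, the regression absorbs part of the imbalance into γ,
shifting that gene's velocity by a constant for every cell; only the
cell-to-cell contrast is directional information, and centering removes
the offset before it can masquerade as coherent flow.  The cost is that
velocity offsets shared by all cells are invisible to the projection,
which is the usual price of the steady-state model.  A state's
outward-flow score is the mean projection of its cells' field vectors
onto the direction from the global embedding centroid to the state
centroid; positive scores mark sources.

## Synthetic data

The generator emulates the study design the pipeline assumes: four
treatment groups of unequal size (352 / 134 / 618 / 696 cells — the
proportions of a sensitive pool, a smaller single-drug-resistant pool
and two larger double-resistant pools, scaled to 1,800 cells), seven
latent expression programs of 150–700 genes each plus 500 background
genes, and group-specific program mixing that moves mass from the first
program (dominant in sensitive cells) toward the late programs in the
double-resistant groups.  Each cell draws one program from its group's
mixing row; its program's genes are up-shifted by an effect size of 2
natural-log units; per-gene baselines are log-normal (SD 0.7 around one
count per cell) with cell-level log-normal noise (SD 0.25); counts are
negative binomial with dispersion θ = 10.  Spliced and unspliced means
obey per-gene ratios γ ~ Uniform(0.5, 3); in the two designated source
states (programs 4 and 5 of 7), the unspliced mean of the program's own
genes is doubled before sampling.  The total count matrix is
spliced + unspliced.  All draws flow from one seed through fixed-offset
substreams.

What the generator does not emulate — and what passing tests therefore
do not establish — includes: batch effects and integration, doublets and
ambient RNA, continuous (rather than discrete-state) differentiation,
gene-gene correlation beyond program co-membership, realistic library-size
variation, and the depth profile of any particular real dataset.  Program
recovery at ARI ≥ 0.9 on this generator shows the pipeline is internally
consistent, not that seven states exist in any real experiment.

## Numerical notes and limitations

- Quantiles use numpy's default linear interpolation; spot thresholds
  compare strictly (`>`).
- Correlation distances are clipped to [0, 2]; zero-variance portrait
  rows correlate as 0 by convention in the distance (their distance is
  1) and as NaN in region correlation.
- The entropy of an empty category is 0 (`0 · ln 0 := 0`).
- Balancing and stratified draws use `numpy.random.default_rng` with the
  config seed; identical inputs and seed give identical kept-cell sets.
- The silhouette criterion can plateau when states are unbalanced or
  overlap heavily; the assignment records the silhouette of every
  candidate k for inspection, and k can be fixed instead.
- Problem sizes used in the shipped tests and the acceptance script
  (1,800 cells, ~3,500 genes, 60×60 grid, 20 epochs) were chosen so the
  full pipeline exercises the default configuration at the study's
  scale; larger inputs should go through the stratified-downsampling
  path first, which is what it is for.
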