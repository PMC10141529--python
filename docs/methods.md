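# Methods

## Model

`treedecon` treats a bulk RNA-seq sample as a non-negative linear
mixture of reference cell-type expression profiles, `Y ≈ B P`, and
estimates the mixing proportions `P` by weighted non-negative least
squares (WNNLS) over a set of selected marker genes. The assumptions
are the usual ones for linear deconvolution: expression adds linearly
across cells on a common linear scale, the reference cell types cover
the material actually present in the bulk samples, and marker-gene
expression in the reference is representative of the bulk tissue up to
the per-gene noise that the weights model.

All algebra is done on linear CPM (counts-per-million). Reference
cells, cluster profiles and bulk columns are normalised identically, so
estimated proportions are invariant to per-sample library size (scale
invariance is asserted directly in the tests). Log scales are never
used in the fit, since NNLS requires additivity.

### Cluster profiles and gene weights

A cluster's profile is the mean of its cells' CPM vectors; subject-level
profiles (the mean over one donor's cells in one cluster) are kept
separately. The per-gene reliability weight is

    w_g = 1 / (1 + CV²_subj(g) + CV²_cell(g))

where `CV²_cell` is the squared coefficient of variation of the gene
across cells within a cluster, averaged over clusters with positive
mean, and `CV²_subj` is the squared CV of the subject-level cluster
means across subjects, averaged over clusters seen in at least two
subjects. Sample standard deviations (ddof = 1) are used. Weights are
bounded in (0, 1]: a gene that is perfectly reproducible across cells
and donors gets weight 1, and increasingly noisy genes are smoothly
down-weighted. Genes with zero mean everywhere receive the minimum
observed weight so degenerate rows can never dominate a fit. Clusters
observed in a single subject contribute no cross-subject term and are
reported with a warning. The weights are computed once from the
reference; no iterative reweighting from residuals is performed by
default (a single pass is well-determined and keeps the fit convex and
deterministic; nothing in our validation indicated a need for
refinement).

### Marker selection

For each target cluster, `n_bs` bootstrap rounds are run. In each
round `n_b` background clusters are drawn uniformly without
replacement, up to `cells_per_cluster_cap` cells (default 100) are
subsampled from the target and from each background cluster to balance
test sizes, and every gene receives a one-sided Wilcoxon rank-sum
p-value for over-expression in the target versus the pooled background
(asymptotic normal approximation with tie correction — deterministic
and fast for the hundreds of tied zero counts typical of single-cell
data). The aggregated score is

    S(g) = median_b ( −log10 max(p_b(g), 1e−300) )

with S(g) set to 0 for genes whose median target-minus-background mean
difference is not positive: a marker must be elevated in its cluster,
because the signature matrix uses it as a positive evidence row. The
median across rounds makes the score robust to extreme background
draws.

The per-cluster count threshold is dynamic. DBSCAN is run on the 1-D
score values with `eps = 3 × MAD` of the *positive* scores (most genes
score exactly 0, so the MAD of all scores would collapse; a 1e−6 floor
guards the fully degenerate case) and `min_samples = 5`. The largest
density cluster is interpreted as the mass of uninformative genes, and
every gene scoring above its maximum — isolated outliers as well as
small high-score clumps — is a marker candidate. Candidates are then
clipped into `[N_min, N_max]` (defaults [28, 35]): excess candidates
are cut by score, shortfalls are topped up with the next-highest
scoring genes, and if fewer than `N_min` genes have positive scores at
all, all of them are returned with a warning. Ties are broken by
lexicographic gene id everywhere, so the selection is a pure function
of the scores.

Genes selected by several clusters are assigned to the cluster where
they scored highest (ties to the lexicographically first label) before
the signature union is formed — signature rows must be unique — which
is why the union can be smaller than K × N_min even when every
per-cluster list is full.

Defaults `n_b = 4`, `n_bs = 100`, bounds `[28, 35]` are the values
selected by the pseudo-bulk tuning loop (`tune_parameters` reproduces
the experiment); the DBSCAN constants are internal robustness
parameters, exposed in `MarkerConfig` but not intended for routine
tuning.

### Tree-guided estimation

Clusters can be organised into a two-level tree of named groups
(e.g. tumour subtypes / crypt states / enterocytes). Estimation then
proceeds in two stages per sample:

1. **Within-group composition.** For each group `G`, the bulk vector
   restricted to the rows of `G`'s own markers is fitted by WNNLS
   against *all* K signature columns; the member-cluster coefficients
   are renormalised to the composition `p_{k|G}`. Fitting all columns
   (rather than only member columns) matters: marker genes of `G` are
   enriched in, but not exclusive to, `G`, and modelling the
   out-of-group signal explicitly prevents it from being absorbed into
   (and biasing) the member estimates.
2. **Group shares.** Composite profiles `b_G = Σ_{k∈G} p_{k|G} B_k`
   are assembled on all marker rows and the full bulk vector is fitted
   against them, giving shares `π_G`. If a group has no usable marker
   rows or an all-zero composition, its pooled (cell-weighted mean)
   profile substitutes for the composite and its share is split evenly
   among members.

The final estimate is `p_k = π_G(k) · p_{k|G}`, renormalised to the
simplex. For singleton groups the procedure reduces exactly to the
flat single-stage fit, and on a noiseless linear mixture of the
reference profiles it recovers the true proportions to machine
precision — the property that anchors the validation suite. The
pooled-profile construction of the coarse signature remains available
(`group_signature`) as the fallback and for inspection.

### Solver and diagnostics

Each WNNLS problem is solved by scipy's deterministic active-set NNLS
(Lawson–Hanson) on the rows rescaled by `sqrt(w_g)`; there is no
randomness in the fit. Raw coefficient magnitudes are kept in
`raw_total` for QC before the simplex renormalisation. An all-zero
bulk vector yields an all-zero, flagged column that is excluded from
the simplex invariant.

Per-sample fit quality is reported as the weighted residual sum of
squares and as a unit-free **deviance**,

    deviance_m = Σ_g w_g (y_g − ŷ_g)² / Σ_g w_g y_g² ,

where `ŷ` is the fitted direction rescaled to the CPM magnitude by a
closed-form scalar least squares. Deviance 0 means perfect
reconstruction; values are comparable across samples and datasets.
This normalisation is this package's convention — reported deviance and
residual figures are therefore comparable only within it.

Bulk and signature genes are intersected case-sensitively before
fitting; below 80 % marker coverage a warning is logged, below 50 % the
fit refuses to run. Marker rows that are zero in every signature
column are dropped with a logged count.

## Synthetic data

The generator emulates the statistical structure the method consumes,
not any particular tissue: per-gene base means drawn log10-uniform over
(−1, 1.5) (≈0.1–30 expected counts, spanning the dynamic range where
rank tests go from powerless to saturated); multiplicative log-normal
per-subject effects (sd 0.25 on the log scale, ≈25–30 % typical
between-donor variation — the stressor the gene weights target);
log-normal per-cell noise (sd 0.2) for extra-Poisson cell-level
variation; negative-binomial counts with dispersion 2 (variance
µ + µ²/2, i.e. strongly overdispersed, as UMI data are); and
`markers_per_cluster` planted markers per cluster whose mean is
multiplied by `marker_fold` (default 8) in that cluster only. Defaults:
2000 genes, 9 clusters, 4 subjects, 40 cells per cluster per subject.

Pseudo-bulk mixtures draw proportions from Dirichlet(α) (default α = 1,
the uniform simplex) and come in two modes: **exact-mixture** columns
are `Σ_k p_k ×` (cluster-k mean CPM profile) — the noiseless generative
identity `Y = B_full P` that defines the fidelity ceiling — and
**cell-sampling** columns sum the counts of cells drawn (with
replacement) at the true cluster frequencies, optionally restricted to
a held-out subject so that recovery is measured across donors. All
randomness flows from explicit integer seeds; marker selection derives
one child stream per cluster keyed by a CRC of the cluster label, so
results are independent of cluster iteration order.

What the generator does *not* emulate: realistic gene–gene correlation,
cluster-specific library sizes, ambient RNA, doublets, or the gene-level
means of any real dataset. Passing the validation suite therefore
demonstrates correctness of the estimation machinery under the stated
generative assumptions, not performance on any particular tissue.

## Validation experiments

The benchmark script (`scripts/acceptance.py`) and the acceptance tests
run two experiments at desk scale on the default synthetic reference,
chosen to keep the full pipeline under a few minutes on one CPU:

- **Noiseless recovery:** 20 exact-mixture samples, deconvolved with
  markers selected at the tuned parameters and the default 4/3/2
  cluster tree; flattened Pearson r between true and estimated
  proportions (observed: r = 1.0, residual sum ≈ 1e−22).
- **Cross-donor recovery:** 20 cell-sampling samples of 500 cells each
  drawn from a held-out subject, averaged over 5 seeds (observed:
  r ≈ 0.91–0.94 depending on seed).

Supporting checks: WNNLS agreement with an exhaustive simplex grid
search (step 0.01) within 0.02 L∞ on 100 random instances; planted
markers recovered with per-cluster Jaccard ≥ 0.9 at fold 8 and chance
overlap at fold 1; per-cluster marker counts within [28, 35] with a
union of at most 315; simplex and byte-level determinism invariants.

## Known limitations

- Two-level trees only; deeper hierarchies would require recursive
  composition.
- Proportions are mRNA proportions: no correction for per-cell-type
  total mRNA content is applied, as none is identifiable from the
  inputs the model takes.
- Gene identifiers are matched as opaque case-sensitive strings; no
  alias or ortholog resolution.
- The rank-sum test's asymptotic approximation is inaccurate for
  clusters with fewer than ~10 cells; such references also make the
  subject-level CVs noisy.
- A single reference is used per fit; ensemble weighting across
  multiple references is out of scope.
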