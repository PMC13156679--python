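# Methods

`scmsi` re-implements, as a tested Python pipeline, a single-cell lipidomic
MALDI mass spectrometry imaging (MSI) analysis of cultured cancer cells
undergoing an EGF-induced epithelial–mesenchymal transition (EMT): from
per-pixel spectra and co-registered brightfield micrographs to
cell-specific lipid features, dispersed/cohesive cell populations,
batch-corrected single-cell matrices, consensus-selected Leiden clusters
and marker lipids. Every stage is exercised end-to-end on a synthetic-data
generator with known ground truth.

## The synthetic experiment

The generator emulates the structure of the assay, not its physics. One
sample is a rectangular MSI grid (default 200×200 pixels at 10 μm pitch)
carrying:

- **Geometry.** `n_singletons` isolated single cells (discs with area
  drawn uniformly in 250–1200 μm², i.e. ~18–39 μm diameter — comfortably
  inside the 100–2500 μm² single-cell filter even after Gaussian blur
  erodes the rendered footprint) and `n_colonies` cohesive colonies
  (unions of 2–4 overlapping discs of radius 3–4.5 MSI pixels; each disc
  alone exceeds 2500 μm², so a colony can never pass the single-cell
  filter). Objects are placed with ≥2.5 background pixels between
  bounding circles, making the dispersed/cohesive ground truth and the
  component-wise evaluation unambiguous.
- **Spectra.** 46 centroided peaks in m/z 500–1000 with ≥3 Da spacing.
  Six are matrix-derived peaks present everywhere at similar intensity
  (these are what the 5× cell-specificity filter must reject); 40 are
  cellular lipid peaks grouped into head-group classes (PA, PS, PE, PI,
  PG, LPI, unassigned). Half of the cellular peaks leak into the
  background at 1/150 of their cellular level, so the filter's ratio is
  computed against non-zero backgrounds. The leak is kept far below 1/5
  because TIC normalization rescales background spectra up by the
  cell/background TIC contrast (~5–10× here), which eats into the
  measured ratio.
- **Effects.** The treatment (EGF) effect map is class-structured:
  −0.6 log2 on 2 PA, 2 PS, 4 PE and 10 PI species, +0.6 log2 on 2 PG
  species and the lyso-PI — 21 affected features, a class structure chosen to match how EMT
  induction reshapes glycerophospholipid head-group levels in this cell
  system. Batches
  (matrix-application pairs) act multiplicatively on whole samples.
  Planted subpopulations shift disjoint 5-feature blocks by
  `separation` × the log2-scale noise SD (default separation 4). Noise
  is log-normal, per pixel and per feature (`noise_cv`, default 0.2),
  plus a per-pixel gain factor; with `noise_cv = 0` the generator is
  exactly deterministic and closed-form checks hold to machine
  precision.

The generator does **not** emulate isotope envelopes, adducts, mass drift
beyond a small per-pixel m/z jitter (0.01 Da), chemical background
gradients, or optical artifacts in the brightfield. Passing tests
therefore demonstrate correctness of the computations, not robustness to
every artifact of real acquisitions.

## Preprocessing

- **TIC normalization** rescales each spectrum to the dataset's mean raw
  TIC (not to 1), preserving the absolute intensity scale the 5× ratio
  filter operates on. Zero-TIC pixels are flagged and left at zero. The
  operation is idempotent.
- **Noise estimation** is 1.4826 × MAD of the residual after running-median
  detrending (window 101 samples; the window is large so that the
  variance inflation from subtracting the running median stays below 2%).
- **Peak picking** reports local maxima with intensity ≥ 6 × noise,
  centroided by three-point parabolic interpolation (shift clipped to
  half a sample).
- **Alignment** pools all per-pixel peak m/z values, sorts them, and opens
  a new feature whenever the gap exceeds 0.1 Da (a typical reflector-TOF
  peak width at this range; configurable). Features observed in <1% of
  pixels are dropped. The result is invariant to pixel order.
- **Cell-pixel detection** runs k-means (k-means++ with 10 restarts, fixed
  seed) on feature vectors augmented with Gaussian-weighted neighborhood
  means (σ = 1 pixel) — a spatially regularized approximation of spatial
  k-means. Pixels are processed in canonical (row, col) order so the
  partition does not depend on input ordering. The cell cluster is the
  one with the highest mean raw TIC, ties broken toward the larger
  cluster. k defaults to 2 (cells vs background); a sweep is available.
- **Cell-specific peaks**: mean(cell pixels) ≥ 5 × mean(background
  pixels), boundary inclusive; a feature absent from background but
  present in cells is retained.

When several samples are analyzed together, per-sample feature centers
are matched across samples by the same greedy gap rule, only features
present in every sample are kept, and the 5× filter verdict is taken by
majority vote across samples.

## Segmentation

Brightfield images are blurred (Gaussian, σ = 5 px, reflective borders)
and binarized with Otsu's 256-bin threshold; cells are the dark side by
default. 8-connected components yield contours; their pixel-count area
and bounding-box width/height ratio feed the single-cell filter
(100–2500 μm² and 0.75–1.25, both inclusive). Accepted contours are
projected onto the MSI grid by an axis-aligned scale + translation
(+optional flips); richer registration is out of scope. MSI cell pixels
covered by exactly one accepted contour take its id; remaining cell
pixels are flood-filled (4-connected) from uniquely adjacent ids. A cell
id is *dispersed* iff its pixels constitute one whole connected component
of the cell mask and that component received exactly one id; all other
cell pixels are *cohesive*. Manual curation steps common in such workflows
are replaced by these deterministic rules plus an optional override
table, which records what would otherwise be manual edits.

## Quantification and batch correction

Observational units are single dispersed cells (one mean spectrum per
cell id), organization pools (cohesive/dispersed per sample), or whole
samples. Batch correction follows the parametric empirical-Bayes
location/scale model (ComBat): log-transform with ε = half the smallest
positive value; per-feature standardization that removes batch and
protects covariate (treatment) effects; normal prior on per-batch
locations and inverse-gamma prior on per-batch scales with
method-of-moments hyperparameters; γ*, δ*² iterated to 1e-6 (≤500
iterations); back-transform restores covariates. A batch with a single
unit receives a location-only correction with a warning; a single batch
returns the input unchanged. The implementation matches the reference R
implementation (sva::ComBat) to ~4e-6 on logged data; the residual is
attributable to the tighter convergence tolerance.

Two measurement notes on parameter recovery at n = 500/batch, documented
because they are properties of the EB model rather than of any
implementation. (1) The post-correction *per-feature* batch variance
ratio retains ~±12% deviations: with a feature-uniform planted scale
effect the inverse-gamma prior is (correctly) strong and δ* shrinks
halfway to the common mean, leaving half the sampling noise of the
per-feature variance estimates; with heterogeneous scale effects the
two-batch standardization constraint (the standardized variances of the
two batches sum to 2 per feature) bounds the cross-feature spread and
keeps the prior strong. The pooled variance ratio is the stable summary
and lands at 1.00 ± 0.02. (2) Treatment-effect preservation is assessed
on the mean estimated log-fold-change across features; per-feature LFC
estimates at this sample size carry sampling noise exceeding 10% of the
planted effect for any estimator.

Scaling is per-feature z-scoring (ddof 1, zero-variance features dropped
with a warning). PCA uses a full SVD with deterministic orientation
(largest-|loading| entry of each component made positive).

## Consensus clustering

The single-cell clustering procedure: on each of `n_iter` iterations
(default 500; parameter-recovery checks use 100) a subsample of
⌈0.8 n⌉ cells is drawn without replacement; for each of 8 neighborhood
sizes (k ∈ {5, 10, 15, 20, 25, 30, 40, 50}) a shared-nearest-neighbor
graph is built (k-NN by Euclidean distance, ties by index, self-inclusive
sets; edge weight = Jaccard index of the neighbor sets — deliberately
simpler and oracle-testable, not the rank-based weight of the original
graph package) and partitioned by Leiden (RB-modularity) at 19
resolutions (0.1–1.9). Each partition is binned by its *realized* cluster
count K; the consensus matrix for K is the co-clustered count over the
co-sampled count. Candidates with fewer than 10 supporting partitions are
discarded; never-co-sampled entries (rare at these settings) are imputed
with the matrix mean and logged. Per-iteration seeds derive from the
master seed by counter, so results do not depend on scheduling.

Each retained consensus matrix is cut by McQuitty/WPGMA hierarchical
clustering (scipy's `weighted` linkage on 1 − consensus) into K clusters;
candidates are ranked by mean silhouette on the top-10-PC embedding
(silhouette convention: singletons and all-zero distances score 0). The
top-ranked K is selected unless the user overrides — in this kind of
analysis the runner-up (e.g. 7 over a trivial treatment split of 2) is
often the scientifically interesting choice, and the ranking plus an
override flag support that decision without hard-coding it. The 8
k-values and 19 resolutions default to a range spanning under- to
over-clustering and are configurable.

## Statistics and markers

Welch's t-test is the default two-sample test; paired t-tests (pairing by
matrix-application round, or by source sample for the cohesive-vs-
dispersed comparison) are one-sample t-tests on differences. Multiple
testing uses Bonferroni over the tested features. IQR overlap uses
type-7 quantiles. A lipid is a marker for a comparison iff all three
hold: fold change > 1.5 or < 0.667 (linear-scale means of unscaled,
batch-corrected intensities), Bonferroni-adjusted Welch p < 0.01, and
non-overlapping IQRs; p < 0.001 is additionally reported as a "strict"
highlight tier. When one cluster is compared against several, the latter
pool with one data point per cell, weighting larger clusters more. qPCR
relative expression is ΔΔCt (fold change 2^(−ΔΔCt)) with per-group
two-sample t-tests against control, Bonferroni-adjusted over groups.

## Problem sizes and determinism

Test-suite simulations use compact slides (80–100 px grids, ~30 objects)
and matrices of a few hundred cells; the parameter-recovery run for the
clustering uses the study-scale configuration (1300 cells, 46 features,
7 subpopulations, 100 consensus iterations, full 8×19 grid), which takes
a few minutes on one CPU. The full default pipeline (200×200 px, 500
iterations) is sized for workstation runs. All randomness flows from
explicit seeds: the same configuration reproduces byte-identical
outputs; t-SNE is used for visualization only.

## Known limitations

- Registration supports scale/translation/flips only; rotated or
  deformed brightfield acquisitions must be rectified upstream.
- Normalization methods beyond TIC are not validated; isotope
  deconvolution, mass recalibration and lipid identification are out of
  scope.
- The consensus procedure's runtime grows with n² per iteration; beyond
  ~5000 cells an approximate nearest-neighbor backend would be needed.
- The marker caller assumes reasonably symmetric within-group
  distributions; heavy-tailed features pass through Welch + IQR rules
  unchanged.
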