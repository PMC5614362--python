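# Methods

This note documents the models and algorithms behind `srseg`, the
parameters that matter, the numerical choices, and what the synthetic
phantoms do and do not establish about real data.

## Data model

A workspace holds one volume in fixed internal (z, y, x) axis order (an
orientation tag permutes the file's axes once, at load), one active region
of interest (ROI, half-open 0-based bounds), named feature channels,
annotation levels and the super-region partitions.  Every derived product
has the ROI's extent; changing the ROI invalidates all derived products,
since channels, partitions and annotations computed for one sub-volume are
meaningless for another.  Non-finite voxels are rejected at load by
default (an opt-in flag replaces them with the volume median); silent
imputation would hide acquisition faults.

The on-disk workspace is a single HDF5 file with groups `data`,
`channels/<name>`, `levels/<id>`, `supervoxels`, `megavoxels`, metadata in
JSON attributes, schema version 1.  This layout is an artifact of this
package, versioned so it can evolve.

## Feature channels

Eight operators produce derived scalar grids; all filtering uses reflect
padding (no wrap-around artifacts on small ROIs; a `boundary` argument
exposes the other scipy modes) and Gaussian kernels truncated at 4σ (the
standard accuracy/cost trade-off).

* **Gaussian** smoothing, σ default 1 (recommended range 0.5–10).
* **Total variation** denoising: Chambolle's dual projection scheme, run
  for exactly `n_iter` iterations (default 100, range 50–500) with no
  early stopping, so the output is a pure function of the parameters.
  `lambda_tv` (default 10, range 0.1–30) is the denoising weight in data
  intensity units — on tomogram-scale intensities (hundreds) the default
  is a mild smoothing.  `spacing_tv` weights the finite-difference
  gradient per (z, y, x) axis; we read it as gradient weighting rather
  than voxel anisotropy, matching its role in the dual update.  The
  isotropic TV norm is used.  An optional `clamp=(lo, hi)` truncates
  intensities *before* denoising, removing extreme values (either bound
  may be open).
* **Threshold**: binary 1 where `vmin ≤ I ≤ vmax`, either bound open.
* **Gaussian centering**: `I − G_σ(I)` (local mean removal), σ default 2.
* **Gaussian normalization**: `(I − G_σ(I)) / sqrt(G_σ((I − G_σ(I))²) + ε)`
  with `ε = 1e−8 · var(I)` — a local z-score, invariant to affine
  intensity rescaling up to ε effects.  These two operators are defined
  here as local-mean removal and local standardisation; the names are
  common in the field but the formulas vary between tools.
* **Laplacian of Gaussian**: negated for `response="bright"` so bright
  blobs score positive; `thresh` zeroes negative responses after the sign
  convention.  Defaults σ 2, no threshold, bright.
* **Difference of Gaussians**: `G_σ(I) − G_(σ·ratio)(I)`, ratio default 1.6.
* **Structure tensor determinant**: Gaussian-derivative gradients at σ₁,
  outer products averaged at σ_area, closed-form 3×3 determinant;
  non-negative up to float error since the tensor is PSD.  Defaults 2/2.

Channels form a DAG (a channel may consume another channel); the queue
computes them in dependency order and recomputation drops dependents.
Values outside the recommended ranges warn but are accepted.

## Supervoxels

SLIC-style clustering, written for determinism:

* Seeds sit at the centers of a regular grid with cell size
  `shape = (sz, sy, sx)`; the product sz·sy·sx is capped at 1024, which
  bounds per-seed search windows and memory.  Each seed is nudged to the
  lowest-gradient voxel of its 3³ neighbourhood to keep it off boundaries.
* 10 fixed assignment/update iterations minimise
  `D² = (ΔI)² + Σ_a (m · spacing_a · Δa / S_a)²` where intensity is the
  source channel rescaled to [0, 1], `S_a = shape_a` normalises the
  spatial term per axis, and `m = compactness / 100` maps the
  conventional compactness range [1, 200] onto a balanced regime (low
  compactness → more deformation; a larger spacing weight on an axis makes
  boundaries along that axis more expensive to cross).  Ties keep the
  lowest region id; there is no randomness anywhere.
* Connectivity is enforced afterwards: per id, the largest 6-connected
  component keeps the id and orphan fragments merge into their most common
  adjacent region (lowest id on ties); ids are then relabelled densely.

Both tiers use 6-connectivity (face adjacency), which is what "boundary"
means for a voxel partition.

## Megavoxels

Each supervoxel gets a `num_bins`-bin normalised intensity histogram of
the source channel (rescaled to [0, 1]).  Merging is greedy hierarchical
agglomeration on the region adjacency graph: repeatedly merge the pair
with the smallest chi-squared histogram distance
`½ Σ (h₁−h₂)²/(h₁+h₂)` (recomputing the merged histogram,
voxel-count-weighted), until the cheapest edge exceeds `lambda_mv`.

This was a genuinely open design point: a scale-adaptive merge test
(Felzenszwalb-style) was considered, but its merge decisions depend on the
threshold, so the megavoxel count is not guaranteed monotone in λ.  With a
stopping-threshold agglomeration the merge *sequence* is independent of λ
— the threshold only truncates it — so "larger λ ⇒ fewer, larger
megavoxels" holds by construction, and "higher num_bins ⇒ finer
distinctions ⇒ smaller megavoxels" follows from the finer histograms.

The optional `gamma` sharpens similarity: edge distances (all in [0, 1])
are mapped `w → w^(1/γ)`, so small γ drives distances toward 0 and merges
more aggressively (fewer megavoxels); γ = 1 is the identity; `"auto"` uses
the median initial edge distance.  Ties break toward the lowest id pair.
A lazy priority queue re-validates stale entries on pop, so the
implementation is exactly equivalent to the quadratic recompute-everything
formulation (tested against it on small instances).

## Annotation

Levels hold one int32 label grid (−1 unlabeled).  Labels may name a parent
on an earlier level; child voxels outside the parent are rejected and
counted, so a hierarchy (cell → organelles) stays consistent.  The pen
footprint is an in-plane (y, x) disk of radius `pen_width` at each seed's
slice — painting is slice-wise in practice, and a 3D ball of the same
radius would claim voxels the annotator never saw.  Supervoxel/megavoxel
modes label every region the footprint touches, whole; that is the point
of super-regions — one click labels thousands of similar voxels, and a
label can never split a supervoxel.  Later strokes overwrite earlier ones
(deterministic last-wins, the painting intuition).

Morphological refinement (dilation, erosion, opening, closing, fill holes;
ball/disk structuring element, radius 1–20, default 1) applies per slice
("all slices 2D", the recommended scope), to one slice, or in 3D.  Voxels
gained by growth only claim unlabeled voxels — refinement never corrupts
adjacent labels — and respect the parent mask; voxels lost become
unlabeled.  A practical cleanup order is fill holes → opening → dilation.

## Model training

Descriptors per region and channel: mean, standard deviation and the
25/50/75th percentiles — five robust, classifier-agnostic statistics, so
k channels give a 5k-column matrix.  Classifiers: random forest (default,
100 trees, range 10–100), SVM with probability calibration, and an online
linear model (SGD, logistic loss); the latter two standardise features and
use library defaults since only the forest's size is conventionally
specified.  All take the run seed; training regions keep their user label
(their probability rows are one-hot), so commitment can never overwrite an
annotation.

Refinement is MAP smoothing on the supervoxel graph: unary `−log p`
(probabilities clipped at 1e−8), pairwise `λ · wᵢⱼ · [xᵢ ≠ xⱼ]` with
`wᵢⱼ = 1` (Potts) or `wᵢⱼ = exp(−Δmean²/2s²)`, `s` the median absolute
neighbour mean difference (appearance — separating similar-looking
neighbours is expensive).  The solver is iterated conditional modes in
fixed region order (≤ 50 sweeps, stop on no change): deterministic,
dependency-light, and adequate at supervoxel-graph scale (hundreds of
nodes); each sweep can only lower the energy, which the implementation
records and the tests assert.  Graph cuts would find deeper minima on
pathological instances but adds nothing measurable here.

Commitment maps the confidence slider c ∈ [0, 100] to the top-two
probability margin: a region is committed iff `(p₁ − p₂) · 100 ≥ c`.
This reproduces both endpoints exactly — c = 0 commits every region to its
best match, c = 100 commits only regions where one class holds all the
probability — and is monotone in between.  An optional sub-box and label
selection restrict what is written.  `iterate_training` loops
train → refine → commit; each round trains on more regions, so accuracy is
non-decreasing in practice; if a round commits nothing new the remainder
is committed at confidence 0, so the loop always terminates fully
labelled.

## Label splitter

Connected components per label (26-connectivity by default so diagonally
touching blobs stay whole; configurable), pooled across the selected
labels; touching objects with different labels stay distinct.  Measures:
average intensity, intensity sd and variance (both surfaced — the terms
are used loosely in practice), voxel volume, calibrated volume (voxel-size
triple from config, default 1.0³), centroid, bounding box, per-axis
extents, all against a chosen query channel.  Rules are conjunctive within
a class and first-match across classes (documented, order-stable); an
optional "others" class catches the rest.  Splits save to an empty level
(voxel-count conserving); statistics export as long-format CSV with all
pairwise scatter plots.

## Synthetic phantoms

The generators emulate the three data regimes the toolkit targets, with
ground truth:

* `make_multiregion` — nested ellipsoids (radii fractions spanning
  1.0–0.45 of the volume, ±8% per-axis eccentricity) with evenly spaced
  class means over [100, 900] and Gaussian noise σ = 50: high-contrast,
  crisply bounded material phases (microCT-like).  Intensities are on a
  reconstructed-tomogram scale so that filter parameters quoted in data
  units behave as on real data.
* `make_organelle_cell` — non-overlapping ellipsoidal blobs (rejection
  sampled with 2-voxel clearance, radii 2.5–size/10, intensities
  500–1000), thin tubes of radius 1–2 voxels, a smooth background
  gradient, and Gaussian noise with σ = std(clean)/SNR, so the realised
  SNR matches the request; SNR ≈ 1.5 emulates cryoET, ≈ 3 cryoSXT.
* A `wedge_blur_sigma` option blurs the clean signal along z as a crude
  stand-in for missing-wedge elongation; faithful Fourier-domain wedge
  simulation (and any physical image formation) is out of scope.

Phantoms are pure functions of their seed and record their generative
primitives, so expected blob volumes are recomputable analytically.

What passing on phantoms does **not** show: real tomograms have
non-Gaussian, correlated noise, reconstruction artifacts, intensity
gradients coupled to structure, and boundaries far subtler than a step
between class means.  The phantoms validate the machinery (boundary
adherence, hierarchy contracts, monotone responses, determinism, the
training loop), not field performance; parameter tuning on real data
remains the user's task, which is why every parameter is exposed and
logged.

## Problem sizes and runtime

Default test/acceptance volumes are 48³–64³ with 8³–10³ supervoxel cells
(≈ 216 regions) — large enough that the hierarchy, classifier and MRF are
exercised at realistic region counts, while a full end-to-end run takes a
few seconds on one CPU.  The algorithms scale to real ROI sizes (the
per-seed windows bound SLIC's cost linearly in volume).

## Known limitations

* ICM finds local energy minima; extreme λ with adversarial unaries can
  lock in a poor labelling (use λ ≈ 10–50 as shipped).
* The megavoxel objective is a histogram-distance agglomeration; it does
  not model texture beyond the intensity histogram.
* Per-voxel training (`region="voxel"`) builds a degenerate one-voxel
  partition and is only practical for small ROIs.
* No GPU paths; no transfer of a trained model across volumes.
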