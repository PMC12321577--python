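# Methods

This note documents the models, conventions and numerical choices behind
gliometry, in the spirit of the methods documentation of simulation and
statistics packages: what each procedure assumes, which knobs matter, and
what passing the synthetic-recovery tests does and does not establish.

## Coordinate and unit conventions

Voxel grids are indexed `(channel, z, y, x)`, 0-based, with voxel centres
at integer indices; physical positions in micrometres are `index × voxel
size`. The default synthetic voxel size is (1.0, 0.2, 0.2) µm — typical
confocal sampling at high magnification with thin (5 µm) stacks. The
region atlas is a 2-D coronal label image (background, MS, dLS, iLS, vLS)
with a unit midline-axis vector; 3-D quantities use a configurable stack
depth (default 5 µm, `stack_depth_um`). Morphometry operates on 2-D
maximum-intensity projections; puncta detection operates in 3-D. Tables
are UTF-8 CSV with '.' decimals; floats are written with `repr` so that
read-back is bit-exact. Configuration is TOML; unknown keys are a hard
error so typos cannot silently fall back to defaults.

## The synthetic-data model

The simulator emulates the assay geometry, not optics in detail:

- **Arbors** are straight-segment stars: `n_branches` (default 6) rays
  from the soma. Branch directions are drawn from a von Mises distribution
  with mean `orientation_mu_deg` (measured from the midline axis) and
  concentration `orientation_kappa`; each direction is then flipped 180°
  with probability 1/2, making arbors axial/bidirectional. The flip leaves
  the folded angle (to [0°, 90°]) unchanged, so κ = 0 yields folded angles
  uniform on [0°, 90°) and large κ yields midline-aligned cells. Branch
  lengths are Normal(mean, sd) truncated at > 1 µm (defaults 40 ± 8 µm,
  the long-branch, midline-aligned phenotype; the isotropic case models
  the lateral-septum phenotype). A cell's true orientation is the
  principal axis of its tip set reflected through the soma, against the
  midline.
- **Rendering**: branches are rasterized as lines of width
  `branch_width_um` (1 µm), dilated and blurred with a Gaussian PSF
  (`psf_sigma_um`, default 0.5 µm); nuclei and nuclear markers are
  Gaussians with σ = half the 3 µm nuclear radius; channels are peak-
  normalized, then background and i.i.d. Gaussian noise are added and the
  result clipped at 0. Branches are drawn in the central z-plane before
  3-D blurring; since morphometry reads max projections, the z-profile of
  the rendering does not affect any measured quantity.
- **Puncta** are homogeneous Poisson fields (`lambda_pre_per_um3`,
  default 0.01/µm³). A Bernoulli(`coloc_fraction`) subset of pre puncta
  receives a post partner displaced uniformly within a ball of radius
  `coloc_radius_um` (0.3 µm); remaining post puncta are an independent
  Poisson field. Spots are rendered as sub-resolution Gaussians
  (`spot_sigma_um` = 0.15 µm) convolved with the PSF, so the observed spot
  scale is `sqrt(spot_sigma² + psf_sigma²)`.
- **Census**: reference-marker⁺ cells are placed uniformly per region and
  are independently double-positive with that region's
  `p_double_positive`. The defaults (MS 0.74, dLS 0.001, iLS 0.02,
  vLS 0.12) follow the observed medial/lateral lineage split used as the
  simulation scenario.
- **Randomness**: one global seed, split into counter-based PCG64
  substreams per cell and per assay, so adding a cell never perturbs
  another cell's draws and every output is exactly reproducible from
  (seed, config). Written OME-TIFFs embed a content-derived UUID so
  repeated runs are byte-identical.

What the simulator does **not** model: photobleaching, autofluorescence,
depth-dependent aberrations, secondary branching (a branching mode exists
but the measured metrics depend only on tips and mask extent), densely
overlapping arbors, or anisotropic nuclei. Recovery on these images
therefore demonstrates correctness of the measurement operators under the
stated geometry, not robustness to every real-tissue artifact.

## Segmentation

Nuclei: multiscale Laplacian-of-Gaussian blob detection on the DAPI max
projection (scales 0.5–1.5× the expected 3 µm radius), centroids refined
by intensity-weighted centre of mass, per-nucleus masks by Otsu within 2×
the detected radius. Arbors: sparse labelling guarantees one cell per
neighbourhood, so the arbor is the connected component above threshold
containing the nucleus centroid (Otsu within an 80 µm window, or the fixed
`arbor_threshold` for noise-free images where Otsu is degenerate), holes
filled. Border-touching cells are flagged and excluded from morphometry by
default because their territories are truncated. Skeletons come from 2-D
topological thinning; endpoint spurs shorter than `min_spur_um` (2 µm, one
nucleus radius) are pruned iteratively, and adjacent junction pixels are
contracted into single branch nodes. Territories are the convex hull of
mask pixel centres (µm), volume = area × stack depth.

## Morphometry numerics

The maximum Feret diameter is computed exactly as the maximum pairwise
distance over convex-hull vertices (the caliper maximum is always attained
at hull vertices); the 0.5°-grid rotation search is retained only as a
test oracle. Width is the full hull extent perpendicular to the Feret
axis — well-defined for asymmetric arbors, unlike a width "through the
nucleus". Cells with L/W below `orientation_min_elongation` (1.1) have no
meaningful axis and are reported with undefined orientation, which binning
skips. Angle bins default to [0°, 30°), [30°, 60°), [60°, 90°] — three
equal bins, so the isotropic expectation is exactly 1/3 per bin; the bin
edges of published pie charts are not standardized, so the edges are
configurable. The longest-branch distance is the maximum Euclidean
distance from the nucleus centroid to a skeleton endpoint; a cyclic
skeleton (no endpoints) falls back to all skeleton voxels and flags the
record. Sholl profiles count sign changes of (distance − r) along each
branch polyline; a vertex exactly on the circle counts once.

## Puncta numerics

Detection is 3-D multiscale LoG at the observed (PSF-convolved) spot
scale, clamped to at least half a voxel per axis where the LoG response
degenerates; sub-voxel centroids come from a per-axis three-point
quadratic fit; detections closer than `min_spot_separation_um` (0.3 µm)
merge keeping the stronger. Colocalization is greedy globally-nearest
one-to-one matching within `coloc_max_dist_um` (default 0.5 µm — within
one optical PSF at the emulated magnification; published MATLAB pipelines
do not state their exact distance rule, so this is a declared
operationalization). One-to-one matching prevents double-counting a post
punctum apposed to several pre puncta; on small instances the greedy pair
count equals the optimal assignment in ≥ 99% of cases and never differs by
more than one (tested against `linear_sum_assignment`). Ties are broken by
(pre_id, post_id) order. A pair's location is the centroid midpoint;
territory membership is a 2-D polygon test with all z accepted within the
thin stack. Synapse densities are reported per mm³ (territory volume);
regional RNAscope heatmaps per unit area normalized to the MS — the two
reporting conventions used for these assays. Puncta-per-nucleus uses 2-D
projected positions (cryosections are read as near-2-D); a spot inside two
margin-dilated masks goes to the nearer centroid, ties to the smaller id.

## Census

Positivity is called against background mean + k·s.d. (k = 3) estimated
outside all dilated nuclear masks, rather than Otsu across cells: a
bimodality-based threshold fails in regions with ~0% or ~100% positives.
A cell's region is the region of its nucleus centroid; boundary cells are
not split. A region with no reference cells reports an undefined (NaN)
fraction, never 0.

## Statistics

One-way ANOVA uses the textbook decomposition
`F = (SS_b/df_b)/(SS_w/df_w)` with the upper-tail F distribution; with two
groups this is exactly the squared pooled t statistic. Tukey's HSD uses
the Tukey–Kramer form for unbalanced groups (the emulated experiments have
19–59 cells per group), with adjusted p from `scipy.stats
.studentized_range` (numerical integration, abs. tolerance ≲ 1e-8); the
suite cross-checks against `scipy.stats.tukey_hsd` and statsmodels.
s.e.m. uses the n−1 standard deviation; quartiles use linear interpolation
(type-7), a convention fixed here for reproducibility. No per-animal
nesting correction is applied — pooled cells are analyzed as independent,
matching common practice in the emulated assays; this is a recorded
limitation, not an endorsement.

## Problem sizes

The recovery tests and `scripts/acceptance.py` run at desk scale chosen to
give stable statistics on one CPU: 30–50 rendered cells for morphometry
recovery, 1 000 vector-level cells for isotropy, 500–1 000 random matching
instances, 20–50 Poisson-field replicates, 5 000 census cells per region,
and 10 000 null simulations for ANOVA calibration. Tolerances are the
sampling-theory bounds (3 standard errors, binomial/Poisson), exact
arithmetic where the quantity is deterministic, and 1e-6–1e-10 where two
computations of the same closed form are compared.

## Known limitations

- 2-D morphometry: metrics are projections; strongly z-oriented branches
  would be under-measured (the emulated stacks are 5 µm thin, where this
  is negligible).
- The convex-hull territory is one operationalization of hand-drawn
  territory outlines; concave territories are over-covered.
- Greedy matching is not guaranteed optimal; the oracle comparison bounds
  the discrepancy at desk scale.
- Detection thresholds are tuned for the synthetic SNR regime; real data
  will need per-dataset threshold configuration via the TOML config.
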