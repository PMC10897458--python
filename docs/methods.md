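# Methods

`smorph` segments spatiotemporal single-molecule localization microscopy
(SMLM) point data into individual protein assemblies and condenses each
assembly into a named morphological feature vector. This note documents
the models, the parameters that matter, the numerical choices, and what
the synthetic data generators do and do not emulate.

## Data model

The universal currency is a localization table: columns `x`, `y` in nm
and optionally `t`, a 0-based integer frame index. Ground-truth-labelled
tables add `assembly_id` (integer, −1 = background noise) and `class`
(morphology label). Tables without `t` run the pipeline in static mode:
temporal refinement is skipped and initial density clustering is final.

Two coordinate transforms are used throughout: the z-score
x̂ = (x − μ)/σ with the sample (n−1) standard deviation, and the MinMax
rescale x̂ = (x − min)/(max − min). Both are recorded as invertible
transform objects; a constant axis raises an error rather than silently
producing NaN.

## Clustering pipeline

1. **Standardization.** Every coordinate axis (including `t` when
   present) is z-scored. All later steps operate in standardized or
   MinMax space, making the pipeline invariant to the physical scale of
   the input.

2. **Initial clustering.** The overall density — point count divided by
   the standardized x-range × y-range, with ranges taken at the
   0.5th–99.5th percentiles so a handful of stray points cannot inflate
   the box — selects the model: below 1500 points per standardized area
   DBSCAN, at or above it HDBSCAN (scikit-learn's implementation).
   Clustering runs on the spatial (x, y) axes: regions of interest are
   spatial objects, and static acquisitions (arbitrary or random frame
   assignments) must yield the same regions. When `dbscan_eps` is left
   unset it derives from the data as 0.7·√(min_samples/(π·density)) —
   the radius at which a uniform background field would hold
   `min_samples` neighbours, shrunk so background points stay sub-core
   while structures about twice the background density become cores.
   All derived values are logged and returned in the result.

3. **Topological failsafe.** If no region is found, the standardized
   locations are 2D-binned (128×128), Gaussian-blurred (σ = 2 bins), and
   thresholded at the level above which 90% of the localization mass
   lies; the connected component holding the most points becomes the
   single region of interest.

4. **Temporal refinement.** Each region — its members plus any
   still-unassigned points inside the region's bounding box expanded by
   `refine_margin` (default 0.3, i.e. 30% per side) — is MinMax-rescaled
   in (x, y, t) and processed frame by frame. The box expansion is what
   lets the refinement recapture the diffuse assembly edges that density
   clustering rejects as noise. A region-specific search range is
   derived from the pairwise distances of the rescaled points: distances
   inside the interquartile range (outward-inclusive order-statistic
   bounds, so boundary ties are kept) are retained, their standard error
   of the mean is taken with the **number of points** as the effective
   sample size — the n(n−1)/2 pairwise distances carry only n
   independent observations, so using the pair count would understate
   the standard error by orders of magnitude and collapse the search
   range — and r_search = √(radius_ratio · SEM) with radius_ratio
   defaulting to the 95% CI factor 1.96. Pairwise distances are computed
   on at most `pdist_max_points` (2000) points, subsampled with a seeded
   RNG after lexicographic sorting so the result is independent of row
   order.

   Frames are visited in ascending order; unassigned accumulated points
   first join an existing sub-assembly when within r_search of an
   already-labelled point (taking the nearest labelled point's label:
   growth takes precedence over seeding), then a DBSCAN with
   eps = r_search and min_samples = `investigate_min_sample` may found
   new seeds among the remaining unassigned points. Labels are never
   revised; whatever is unassigned after the last frame is noise.
   Regions smaller than 4·`investigate_min_sample` skip refinement and
   pass through unsplit: a MinMax-rescaled handful of points always
   spans the full unit interval in t, so the frame-iterative machinery
   is meaningless there (static sparse structures would otherwise be
   deleted wholesale).

5. **Smart density filter.** Up to 500 points are sampled (seeded) from
   the noise left by the initial clustering; each sampled point's local
   density k/(π·d_k²) (k-th-nearest-neighbour estimate, k =
   `density_k`, default 10, computed in standardized spatial
   coordinates against the full table) enters a baseline = mean + 1 SD
   of the densities above their 25th percentile. A candidate assembly
   survives `strict` filtering iff its mean member density exceeds the
   baseline **and** it has at least `final_min_points` members;
   `lose` requires either, `none` neither. With no noise available the
   baseline is 0 (logged) and the filter reduces to the size rule.

### Named profiles

The `default` profile carries broadly well-performing values; the other
profiles are the published per-treatment presets: `isotropic`
(cluster_selection_epsilon 0.05, investigate_min_sample 25), `random`
(investigate_min_sample 25), `fibril` (min_cluster_size 60, min_samples
30, cluster_selection_epsilon 0, radius_ratio 1, and an explicit
dbscan_eps 0.1 for the low-density branch), and `sparse-4/8/15/25`
(dbscan min_samples 3/5/7/10, density_k 3, dbscan_eps 0.07 standardized
units ≈ 61 nm in the protocol's 3 µm region — about three times the
20 nm structure spread scale, well inside the gap between intra- and
inter-structure distances — and a final size filter of >5 points,
relaxed to ≥3 in 4-point mode). Unprinted defaults (HDBSCAN
min_cluster_size 200, rough/final_min_points 50/20, refine_margin,
density_k) were fixed empirically on the simulation suites and are all
overridable per call, per profile file, or via the CLI.

## Morphological fingerprint

Each extracted assembly's (x, y) points are centred and rotated so the
major principal axis lies along x, with the sign fixed by requiring
non-negative third moments — a deterministic alignment that makes every
feature rigid-motion invariant. Coordinates are **not** variance-scaled:
per-axis z-scoring would erase the anisotropy the fingerprint is meant
to measure, and the geometric features keep physical units so that area
converts to a radius in nm.

* **Geometric (3).** Delaunay triangulation; a lognormal is fitted to
  the edge lengths by log-moment matching and edges beyond the fitted
  95% right tail are pruned; `Area` sums the triangles whose edges all
  survive, `density` = N/Area, `max_extent` is the largest pairwise
  distance. The surviving-edge cutoff doubles as the radius of the graph
  stage.
* **Graph (25+, incl. the optional density-fit triplet).** A
  radius-neighbour graph at that cutoff and its minimum spanning tree
  yield degree, component, and edge-length statistics, MST leaf and
  depth statistics, the weighted diameter `longest_shortest_path`
  (double-sweep Dijkstra on the largest component — exact on trees, a
  tight lower bound otherwise), and the straightness ratios `L_s_ratio`
  (shortest graph path between the two max-extent endpoints over the
  extent) and `L_l_ratio` (the unique MST path between them over the
  extent; a true longest simple path is NP-hard). `mu_N`, `sig_N`,
  `W_N` are the moment fit (mean, SD, modal weight) of the per-point
  local-density histogram; they are optional because ring-calibration
  analyses omit them. Sparse graph algorithms (scipy.sparse.csgraph)
  keep large assemblies tractable; the mean clustering coefficient is
  sampled on ≤300 nodes for graphs above that size.
* **Circularity (5).** The blurred 2D histogram (64×64 bins, σ = 2
  bins) is thresholded at the level enclosing 90% of the localization
  mass; the largest connected region's marching-squares contour —
  padded so it closes at the array edge and simplified at one bin width
  to remove pixel jitter — gives the isoperimetric quotient 4πA/P²,
  contour aspect ratio, radial coefficient of variation, solidity, and
  equivalent-circle radius ratio. All five are scale-free. Below 10
  points the convex hull substitutes for the contour (flagged).
* **Symmetry (7).** Quadrant count fractions about the centre of mass:
  max/min ratio (with +1 smoothing so it stays finite), normalized
  entropy, left/right and up/down count balances, per-axis extent
  balances, and the absolute diagonal contrast. Absolute values keep
  every feature mirror-invariant.

Degenerate inputs (collinear points, empty contours) produce flagged
sentinel values, never exceptions, so batch fingerprinting runs to
completion. The registry is versioned; feature order is fixed.

## Downstream analytics

Fingerprints are median-imputed (flagged sentinels), z-scored, embedded
with seeded UMAP (3 components, n_neighbors 5, min_dist 0.1 by default;
named recipes carry the published alternatives, including both printed
insulin grouping eps values 0.7 and 1.0 as separate presets), and
grouped with DBSCAN. Feature ranking uses random-forest impurity or
permutation importances normalized to sum to one. Ring-like assemblies
quantify as r = √(Area/π) per assembly with a Gaussian
maximum-likelihood population fit: μ_r is the sample mean, σ_r the ML
(ddof = 0) standard deviation, diameter d = 2μ_r with propagated
σ_d = √(4σ_r²) = 2σ_r.

## Synthetic data

All generators are pure functions of (parameters, RNG): a fixed seed
reproduces output byte-identically. Movies place assemblies at uniform
origins in a 40 × 40 µm field of view, onsets uniform in the first 300
frames, lifetimes ≥ 100 frames within a 400-frame movie.

* **Isotropic growth.** Per frame, Uniform{0..30} new points are drawn
  from a Gaussian KDE refitted to all current points with bandwidth
  ((f − f_start)/(f_end − f_start)·f_end + 1)·10 nm — 10 nm at onset,
  growing linearly with the assembly's own age; f_end is the assembly's
  end frame. One seed point sits at the origin at onset.
* **Steric hindrance ("random").** Per frame, each of the last ≤50
  points proposes a candidate displaced by an isotropic Gaussian of one
  working unit (100 nm; configurable); candidates are ranked by
  hindrance Σ exp(−d²) over those neighbours (d in working units) and
  the Poisson(10) lowest-hindrance candidates are accepted, producing
  branched, asymmetric structures.
* **Fibril.** A directed walk: per frame each active branch elongates by
  Poisson(1) points with step length ~ N(100, 20²) nm and direction
  ~ N(previous, (π/4)²); each added point branches with probability
  0.5% (≤3 branch events per fibril), the branch direction
  ~ N(previous ± π/4, (π/16)²) with the side a fair Bernoulli draw.
* **Sparse structures.** Short fibrils (elongation 20 ± 5 nm,
  consecutive frames) and static Gaussian ellipses (σ = 10 and 20 nm,
  random rotation, uniformly random frames) at 4–25 points in a 3 µm
  region.
* **Blinking.** Every ground-truth point is replaced by Uniform{1..6}
  detections displaced by Gaussian errors whose σ is drawn per detection
  from LogNormal(3, 0.28) on the log scale (median ≈ 20 nm); originals
  are discarded.
* **Noise.** `uniform` mode appends points uniform in x, y, t; the
  amount defaults to 30% of the signal count (the robustness studies
  sweep it). `heterogeneous` mode places 5–25 seeds uniformly, each
  contributing 20–50 points at σ = 320 nm, then displaces every noise
  point by a magnitude ~ N(20000, 100²) nm along a uniformly random
  direction, clipped to the field of view; a literal per-axis shift
  would translate the noise coherently instead of breaking its
  uniformity. Heterogeneous noise frames are drawn uniformly. Noise
  rows never alter signal rows.
* **Morphing sequences.** Consecutive structures are matched by
  minimum-cost assignment after centroid alignment (the smaller set
  padded by seeded resampling) and linearly interpolated at fractions
  strictly between 0 and 1 — 90 structures with 100 interpolants give
  8900 intermediates. The alternative published protocol (125 assemblies
  in 25 intervals, pruned to 200 points) is reachable through the same
  function's parameters; neither is hard-coded. `reverse_time` maps
  t ↦ max(t) − t for shrinking-structure studies.

### What the generators do not emulate

No photophysics (on/off kinetics, point-spread rendering, camera
noise), no drift, no detection-efficiency gradients. Passing the
simulation studies therefore demonstrates the pipeline's behaviour
under the stated density, growth, and noise structure — not under every
artefact of a real microscope.

## Evaluation

Each ground-truth assembly is matched to the predicted cluster sharing
most of its points, greedily by descending overlap, one-to-one, ties to
the smaller predicted id (the matching is isolated so a Hungarian
variant can be substituted). Per assembly: TP = points in the matched
cluster, FN = points predicted noise, FP = points in any other cluster;
accuracy = TP/(TP+FP+FN). Precision, recall, and F1 aggregate micro
(pooled counts), macro (mean over assemblies — the headline
aggregation), or weighted (TP-weighted). Undefined denominators score 0
with an explicit flag. Correctly-predicted noise contributes to no
count; there is no meaningful TN at the assembly level. Onset offsets
are |earliest frame of the matched cluster − true onset| per matched
assembly; both mean and median are reported since headline summaries
use either.

## Problem sizes

The bundled test suite runs 4 movies per class and the reproduction
script (`scripts/acceptance.py`) 6 per class by default; both expose
the count so the full 50-movies-per-class protocol is one argument
away. Fingerprinting in the classification study subsamples assemblies
to ≤1500 points (seeded); shape features are stable well below that.

## Known limitations

* Spatially crossing fibrils whose growth also overlaps in time can be
  absorbed into one cluster: once a fibril tip point takes the
  neighbour's label, the radius-based growth propagates it down the
  rest of the strand. This lowers the fibril suite's macro F1 and the
  extracted-assembly census relative to a perfect segmentation; the
  event is genuinely locally ambiguous under a radius rule.
* Under the documented steric working unit the simulated "random"
  assemblies are dense and sharp-edged, and the pipeline segments them
  nearly perfectly — above the published accuracy band for that class.
* The diffuse edge of late-stage isotropic growth sits below the noise
  density; those localizations are the dominant loss mode of the
  isotropic suite (lower recall, high precision).
* The pipeline does not track laterally mobile clusters and ignores any
  z coordinate.
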