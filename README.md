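# smorph

Self-parameterizing spatiotemporal clustering and morphological
fingerprinting for single-molecule localization microscopy (SMLM) point
data.

Time-resolved SMLM experiments on protein aggregation produce tables of
localizations — (x, y) positions in nm with a frame index t — in which
individual assemblies (spherulites, amorphous aggregates, fibrils)
overlap in space, grow at different times, and sit in substantial
background noise. `smorph` addresses two questions for researchers
working with such data:

1. **Which localizations belong to which assembly?** A clustering
   pipeline that derives its own parameters from the data: z-score
   standardization; density-based initial clustering (DBSCAN below 1500
   points per standardized area, HDBSCAN above); a topological failsafe
   for pathological inputs; frame-iterative temporal refinement that
   splits spatially overlapping assemblies by growth onset using a
   region-specific search range r_search = √(1.96 · SEM) derived from
   the interquartile pairwise distances; and a smart density filter
   that rejects candidates indistinguishable from background (baseline
   = mean + 1 SD of sampled noise densities above their 25th
   percentile).
2. **What shape is each assembly?** A 40+-feature morphological
   fingerprint in four families — geometric (Delaunay interior Area,
   density, extent), graph network (radius-graph and minimum-spanning-
   tree statistics, the longest shortest path, straightness ratios
   L_s_ratio/L_l_ratio), circularity (isoperimetric quotient and other
   contour ratios), and symmetry (quadrant balances) — suitable for
   embedding (UMAP), group discovery (DBSCAN), feature ranking, and
   ring-diameter quantification r = √(A/π), σ_d = 2σ_r.

Ground-truth-labelled simulators for three growth classes (isotropic
KDE growth, steric-hindrance Monte-Carlo growth, branching fibrils),
sparse nanostructures, blinking corruption, and uniform/heterogeneous
noise make every stage testable without experimental data, and
localization-level scoring (per-assembly accuracy TP/(TP+FP+FN),
micro/macro/weighted precision/recall/F1, growth-onset offsets) closes
the loop. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from smorph import cluster, load_profile, score_clustering, simulate

spec = simulate.MovieSpec(n_assemblies={"isotropic": 10}, seed=1)
movie = simulate.assemble_movie(spec)          # 39195 localizations
config = load_profile("isotropic")             # published treatment preset
result = cluster(movie.table[["x", "y", "t"]], config)
report = score_clustering(result.labels, movie.table["assembly_id"].to_numpy())
print(result.n_clusters)                       # 10
print(round(np.median(report.accuracies), 2))  # 0.73
print(round(report.f1["macro"], 2))            # 0.85
```

Ten isotropically growing assemblies (plus 30% uniform noise) are
simulated in a 40 × 40 µm field of view; the pipeline selects HDBSCAN,
recovers all ten, and scores a median per-aggregate accuracy of 0.73 —
the loss is concentrated in the diffuse low-density edges — with a
macro F1 of 0.85 across assemblies. The scripts in `examples/` walk
through the other capabilities one at a time (fingerprinting the three
morphology classes, embedding and group discovery, ring-diameter
quantification, blinking robustness and sparse 4-detection recovery);
each prints the numbers it computes and what they mean.

For shell use the same stages are available as a thin CLI:

```bash
smorph simulate --class isotropic --n-movies 1 --seed 1 --out movies/
smorph cluster --in movies/isotropic_000.csv --profile isotropic \
       --out labels.csv --report report.json
smorph fingerprint --in labels.csv --out fingerprints.csv
smorph analyze --fingerprints fingerprints.csv --recipe generic --out groups.csv
smorph evaluate --pred labels.csv --truth movies/isotropic_000.csv --out metrics.json
```

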