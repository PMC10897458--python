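"""Self-parameterizing spatiotemporal clustering of localization tables.

The pipeline turns raw (x, y[, t]) localizations into per-point assembly
labels in five stages:

1. **Standardization** — z-score of every coordinate axis, making all
   later steps invariant to the physical scale of the input.
2. **Initial clustering** — DBSCAN or HDBSCAN, chosen agnostically from
   the overall point density (fewer than 1500 points per standardized
   x-y area selects DBSCAN), yielding rough regions of interest.
3. **Topological failsafe** — if no region is found, a Gaussian-blurred
   2D density map is thresholded at its 90th percentile and the largest
   contour region becomes the single region of interest.
4. **Temporal refinement** — each region is MinMax-rescaled (x, y, t) and
   processed frame by frame: points join an existing assembly when within
   a data-derived search range of an already-labelled point, otherwise a
   DBSCAN at that same range may found a new assembly seed.  The search
   range r_search = sqrt(radius_ratio * SEM) derives from the standard
   error of the interquartile pairwise distances of the region.
5. **Smart density filter** — candidate assemblies survive only if their
   mean local density exceeds the background baseline (mean + 1 SD of
   sampled noise-point densities above their 25th percentile) and/or a
   minimum size, per ``filter_mode``.

Every auto-derived parameter (model choice, per-region search range,
density baseline) is logged at INFO and returned in the result so the
"agnostic" decisions stay auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, label as ndi_label
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN, HDBSCAN
from sklearn.neighbors import NearestNeighbors

from .config import PipelineConfig
from .io import standardize, minmax_scale, validate_table, DegenerateAxisError

__all__ = [
    "ClusterResult",
    "ZeroSpreadError",
    "select_initial_model",
    "topological_failsafe",
    "compute_search_range",
    "temporal_refinement",
    "local_densities",
    "smart_density_filter",
    "cluster",
]

log = logging.getLogger(__name__)

NOISE = -1

#: model-selection threshold: points per standardized x-y area below which
#: DBSCAN handles the initial clustering, at/above which HDBSCAN does.
DENSITY_MODEL_THRESHOLD = 1500.0


class ZeroSpreadError(ValueError):
    """All pairwise distances identical: the search range is undefined."""


@dataclass
class ClusterResult:
    """Per-point labels plus per-assembly provenance and derived parameters."""

    labels: np.ndarray  # -1 noise, 0..K-1 assemblies
    assemblies: pd.DataFrame  # label, region, seed_frame, n_points, density, verdicts
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels[self.labels != NOISE])))


# ------------------------------------------------------------ stages 2 and 3


def select_initial_model(std_table: pd.DataFrame, config: PipelineConfig):
    """Choose DBSCAN vs HDBSCAN from the standardized spatial density.

    Density is N divided by the standardized x-range × y-range; strictly
    below 1500 selects DBSCAN, otherwise HDBSCAN.  Returns
    ``(model_kind, region_labels)``.
    """
    if len(std_table) == 0:
        raise ValueError("cannot cluster an empty table")
    cols = ["x", "y"]
    if config.initial_dims == "spatiotemporal" and "t" in std_table.columns:
        cols = ["x", "y", "t"]
    xy = std_table[cols].to_numpy()
    # density always measured per standardized x-y area; robust ranges so a
    # handful of far outliers cannot deflate it
    lo, hi = np.percentile(std_table[["x", "y"]].to_numpy(), [0.5, 99.5], axis=0)
    area = (hi[0] - lo[0]) * (hi[1] - lo[1])
    density = len(xy) / area if area > 0 else np.inf
    use_dbscan = density < DENSITY_MODEL_THRESHOLD
    if config.initial_model != "auto":
        use_dbscan = config.initial_model == "dbscan"
    if use_dbscan:
        kind = "dbscan"
        eps = config.dbscan_eps
        if eps is None:
            # radius at which a uniform field of the observed density holds
            # min_samples neighbours, shrunk by 0.7: background points then
            # average ~0.49 * min_samples neighbours and stay sub-core,
            # while structures ~2x denser than background become core
            if np.isfinite(density) and density > 0:
                eps = 0.7 * np.sqrt(config.dbscan_min_samples / (np.pi * density))
            else:
                eps = 0.1
        model = DBSCAN(eps=eps, min_samples=config.dbscan_min_samples)
        labels = model.fit_predict(xy)
        log.info("initial DBSCAN eps=%.4f (auto=%s)", eps, config.dbscan_eps is None)
    else:
        kind = "hdbscan"
        try:
            labels = HDBSCAN(
                min_cluster_size=config.hdbscan_min_cluster_size,
                min_samples=config.hdbscan_min_samples,
                cluster_selection_epsilon=config.cluster_selection_epsilon,
                copy=True,
            ).fit_predict(xy)
        except TypeError:
            # scikit-learn's epsilon search can fail on some condensed trees
            # when min_samples is set explicitly; fall back to epsilon 0
            log.warning("HDBSCAN epsilon search failed; retrying with "
                        "cluster_selection_epsilon=0")
            labels = HDBSCAN(
                min_cluster_size=config.hdbscan_min_cluster_size,
                min_samples=config.hdbscan_min_samples,
                cluster_selection_epsilon=0.0,
                copy=True,
            ).fit_predict(xy)
    log.info(
        "initial clustering: density=%.1f pts/std-area -> %s (%d regions)",
        density, kind, len(np.unique(labels[labels != NOISE])),
    )
    return kind, labels


def topological_failsafe(std_table: pd.DataFrame, config: PipelineConfig) -> np.ndarray:
    """Recover one region when initial clustering found none.

    The standardized x-y locations are 2D-binned, Gaussian-blurred, and
    thresholded at the 90th percentile of the blurred counts; the
    connected above-threshold component holding the most points becomes
    region 0, everything else noise.
    """
    xy = std_table[["x", "y"]].to_numpy()
    bins = config.failsafe_bins
    from .fingerprint import density_mass_threshold

    hist, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1], bins=bins)
    blurred = gaussian_filter(hist, sigma=config.failsafe_sigma)
    # top-density region holding `failsafe_percentile`% of the localizations
    thr = density_mass_threshold(blurred, config.failsafe_percentile / 100.0)
    mask = blurred >= thr
    comp, n_comp = ndi_label(mask)
    ix = np.clip(np.searchsorted(xe, xy[:, 0], side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(ye, xy[:, 1], side="right") - 1, 0, bins - 1)
    point_comp = comp[ix, iy]
    if n_comp == 0:  # pathological flat histogram; keep everything
        return np.zeros(len(xy), dtype=int)
    counts = np.bincount(point_comp, minlength=n_comp + 1)
    best = int(np.argmax(counts[1:]) + 1)
    labels = np.where(point_comp == best, 0, NOISE)
    log.info("topological failsafe: %d/%d points in largest density contour",
             int((labels == 0).sum()), len(labels))
    return labels


# ----------------------------------------------------------- stage 4 helpers


def compute_search_range(
    scaled_points: np.ndarray,
    radius_ratio: float = 1.96,
    max_points: int = 2000,
    rng: np.random.Generator | None = None,
) -> float:
    """Region-specific search range from interquartile pairwise distances.

    Pairwise distances within the IQR (Q1 <= d <= Q3, inclusive) are
    kept and their standard error of the mean taken with the *number of
    region points* as the effective sample size — the n(n-1)/2 distances
    derive from only n independent observations, so using the pair count
    would drastically understate the SE.  Then
    r_search = sqrt(radius_ratio * SEM), the 95% CI factor 1.96 by
    default.  Points are subsampled (seeded) to ``max_points`` before the
    O(n^2) distance computation.
    """
    pts = np.asarray(scaled_points, float)
    if len(pts) < 3:
        raise ValueError("search range needs at least 3 points")
    if len(pts) > max_points:
        rng = rng or np.random.default_rng(0)
        # sort rows first so the seeded subsample is independent of the
        # caller's row order (permutation invariance of the pipeline)
        pts = pts[np.lexsort(pts.T)]
        pts = pts[rng.choice(len(pts), max_points, replace=False)]
    d = pdist(pts)
    # outward-inclusive quartiles: order statistics bracketing the IQR, so
    # "within the IQR" keeps boundary distances
    q1 = np.percentile(d, 25, method="lower")
    q3 = np.percentile(d, 75, method="higher")
    kept = d[(d >= q1) & (d <= q3)]
    spread = kept.std(ddof=1) if len(kept) > 1 else 0.0
    if spread <= 1e-12 * max(kept.mean(), 1e-300):
        raise ZeroSpreadError("all interquartile pairwise distances identical")
    sem = spread / np.sqrt(len(pts))
    return float(np.sqrt(radius_ratio * sem))


def temporal_refinement(
    region: pd.DataFrame,
    config: PipelineConfig,
    r_search: float | None = None,
) -> np.ndarray:
    """Split one region into temporally coherent sub-assemblies.

    The region is MinMax-rescaled in (x, y, t) and processed frame by
    frame, lowest first.  Unlabelled accumulated points first join an
    existing sub-assembly when within ``r_search`` of an already-labelled
    point (taking the label of the nearest one), then a DBSCAN
    (eps = r_search, min_samples = investigate_min_sample) on the
    remaining unlabelled points may found new seeds.  Labels are never
    revised; points still unlabelled after the last frame are noise.

    A region without a time axis (static mode) is returned unsplit.
    """
    n = len(region)
    if "t" not in region.columns or region["t"].nunique() <= 1:
        return np.zeros(n, dtype=int)
    cols = ["x", "y", "t"]
    try:
        scaled, _ = minmax_scale(region[cols])
    except DegenerateAxisError:
        # spatially degenerate region: nothing to refine
        return np.zeros(n, dtype=int)
    pts = scaled[cols].to_numpy()
    if r_search is None:
        try:
            r_search = compute_search_range(
                pts, config.radius_ratio, config.pdist_max_points,
                np.random.default_rng(config.seed),
            )
        except (ZeroSpreadError, ValueError):
            # too few / perfectly regular points: nothing to refine
            return np.zeros(n, dtype=int)
    t = region["t"].to_numpy()
    order_frames = np.unique(t)
    labels = np.full(n, NOISE)
    next_label = 0
    for f in order_frames:
        unl = np.flatnonzero((labels == NOISE) & (t <= f))
        if len(unl) == 0:
            continue
        lab = np.flatnonzero(labels != NOISE)
        # growth of existing assemblies takes precedence over new seeds
        if len(lab):
            nn = NearestNeighbors(n_neighbors=1).fit(pts[lab])
            dist, idx = nn.kneighbors(pts[unl])
            join = dist[:, 0] <= r_search
            labels[unl[join]] = labels[lab[idx[join, 0]]]
            unl = unl[~join]
        if len(unl) >= config.investigate_min_sample:
            sub = DBSCAN(eps=r_search, min_samples=config.investigate_min_sample)
            sub_labels = sub.fit_predict(pts[unl])
            for s in np.unique(sub_labels[sub_labels != NOISE]):
                labels[unl[sub_labels == s]] = next_label
                next_label += 1
    return labels


# ----------------------------------------------------------------- stage 5


def local_densities(query: np.ndarray, reference: np.ndarray, k: int = 10) -> np.ndarray:
    """Local point density k / (pi * d_k^2) with d_k the k-th NN distance."""
    k = min(k, len(reference) - 1)
    if k < 1:
        return np.full(len(query), np.nan)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(reference)
    dist, _ = nn.kneighbors(query)
    dk = dist[:, k]  # first column is the point itself (distance 0)
    with np.errstate(divide="ignore"):
        return k / (np.pi * dk**2)


def smart_density_filter(
    candidates: pd.DataFrame,
    member_density: np.ndarray,
    noise_density_sample: np.ndarray,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Apply the density + size filter to candidate assemblies.

    The noise baseline is mean + 1 SD of the sampled noise-point
    densities above their 25th percentile.  ``strict`` requires density
    > baseline AND size >= final_min_points; ``lose`` requires either;
    ``none`` passes everything.  Returns the candidate table with
    ``density``, ``passed_density``, ``passed_size`` and ``kept`` filled.
    """
    out = candidates.copy()
    out["density"] = member_density
    if len(noise_density_sample):
        q25 = np.percentile(noise_density_sample, 25)
        top = noise_density_sample[noise_density_sample > q25]
        if len(top) == 0:
            top = noise_density_sample
        baseline = float(top.mean() + top.std(ddof=1 if len(top) > 1 else 0))
    else:
        baseline = 0.0
        if config.filter_mode != "none":
            log.warning("no noise points to estimate density baseline; "
                        "filter reduces to the size rule")
    out["passed_density"] = out["density"] > baseline
    out["passed_size"] = out["n_points"] >= config.final_min_points
    if config.filter_mode == "strict":
        out["kept"] = out["passed_density"] & out["passed_size"]
    elif config.filter_mode == "lose":
        out["kept"] = out["passed_density"] | out["passed_size"]
    else:
        out["kept"] = True
    out.attrs["density_baseline"] = baseline
    log.info("smart density filter: baseline=%.3g, kept %d/%d candidates",
             baseline, int(out["kept"].sum()), len(out))
    return out


# ------------------------------------------------------------- orchestration


def cluster(table: pd.DataFrame, config: PipelineConfig | None = None) -> ClusterResult:
    """Run the full pipeline on a localization table.

    Deterministic given (table, config): the only stochastic step — the
    500-point noise subsample of the density filter — is seeded from
    ``config.seed``.
    """
    config = config or PipelineConfig()
    table = validate_table(table.reset_index(drop=True).copy())
    if len(table) == 0:
        raise ValueError("cannot cluster an empty table")
    rng = np.random.default_rng(config.seed)
    has_t = "t" in table.columns

    coord_cols = ["x", "y", "t"] if has_t else ["x", "y"]
    std_table, _ = standardize(table[coord_cols])
    xy_std = std_table[["x", "y"]].to_numpy()

    model_kind, region_labels = select_initial_model(std_table, config)
    used_failsafe = False
    if not np.any(region_labels != NOISE):
        region_labels = topological_failsafe(std_table, config)
        used_failsafe = True

    # noise densities for the smart filter come from the *initial* noise
    initial_noise = np.flatnonzero(region_labels == NOISE)
    sample = (
        rng.choice(initial_noise, min(500, len(initial_noise)), replace=False)
        if len(initial_noise)
        else np.array([], dtype=int)
    )
    noise_densities = (
        local_densities(xy_std[sample], xy_std, config.density_k)
        if len(sample)
        else np.array([])
    )

    labels = np.full(len(table), NOISE)
    meta = []
    search_ranges = {}
    next_label = 0
    xy_raw = table[["x", "y"]].to_numpy()
    unassigned = region_labels == NOISE
    for rid in np.unique(region_labels[region_labels != NOISE]):
        members = np.flatnonzero(region_labels == rid)
        if len(members) < config.rough_min_points:
            continue
        # refinement runs on the region plus still-unclaimed points inside
        # its (slightly expanded) bounding box, so the radius-neighbour
        # growth step can recapture diffuse edges the initial clustering
        # dropped as noise
        lo = xy_raw[members].min(axis=0)
        hi = xy_raw[members].max(axis=0)
        pad = config.refine_margin * (hi - lo)
        in_box = np.all((xy_raw >= lo - pad) & (xy_raw <= hi + pad), axis=1)
        idx = np.flatnonzero(
            (region_labels == rid) | (unassigned & in_box & (labels == NOISE))
        )
        region = table.iloc[idx]
        if len(members) < 4 * config.investigate_min_sample:
            # too small for the frame-iterative machinery to be meaningful
            # (a MinMax-rescaled handful of points always spans [0, 1] in t);
            # pass the region through unsplit, filters still apply
            sub = np.full(len(idx), NOISE)
            sub[np.isin(idx, members)] = 0
        elif has_t:
            try:
                scaled, _ = minmax_scale(region[["x", "y", "t"]])
                r_search = compute_search_range(
                    scaled.to_numpy(), config.radius_ratio,
                    config.pdist_max_points, np.random.default_rng(config.seed),
                )
            except (DegenerateAxisError, ZeroSpreadError, ValueError):
                r_search = None
            search_ranges[int(rid)] = r_search
            sub = temporal_refinement(region, config, r_search)
            log.info("region %d: %d+%d points, r_search=%s, %d sub-assemblies",
                     rid, len(members), len(idx) - len(members), r_search,
                     len(np.unique(sub[sub != NOISE])))
        else:
            sub = np.full(len(idx), NOISE)
            sub[np.isin(idx, members)] = 0
        for s in np.unique(sub[sub != NOISE]):
            chosen = idx[sub == s]
            labels[chosen] = next_label
            meta.append(
                {
                    "label": next_label,
                    "region": int(rid),
                    "seed_frame": int(table["t"].iloc[chosen].min()) if has_t else -1,
                    "n_points": int(len(chosen)),
                }
            )
            next_label += 1

    candidates = pd.DataFrame(
        meta, columns=["label", "region", "seed_frame", "n_points"]
    )
    if len(candidates):
        member_density = np.array(
            [
                float(np.mean(local_densities(
                    xy_std[labels == row["label"]], xy_std, config.density_k
                )))
                for _, row in candidates.iterrows()
            ]
        )
        verdicts = smart_density_filter(candidates, member_density, noise_densities, config)
    else:
        verdicts = candidates.assign(
            density=pd.Series(dtype=float), passed_density=pd.Series(dtype=bool),
            passed_size=pd.Series(dtype=bool), kept=pd.Series(dtype=bool),
        )

    # compact final labels: kept assemblies renumbered 0..K-1
    final = np.full(len(table), NOISE)
    mapping = {}
    for _, row in verdicts.iterrows():
        if row["kept"]:
            mapping[row["label"]] = len(mapping)
    for old, new in mapping.items():
        final[labels == old] = new
    verdicts["final_label"] = verdicts["label"].map(mapping).fillna(NOISE).astype(int)

    params = {
        "model": model_kind,
        "used_failsafe": used_failsafe,
        "search_ranges": search_ranges,
        "density_baseline": verdicts.attrs.get("density_baseline", np.nan),
        "config": config,
    }
    return ClusterResult(labels=final, assemblies=verdicts, params=params)
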