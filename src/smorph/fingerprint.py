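"""Morphological fingerprinting of extracted assemblies.

One assembly's point set is condensed into a named vector of 40+ scalar
features across four families:

* **geometric** (3) — interior area from a Delaunay triangulation whose
  long edges are pruned at the 5% right tail of a fitted lognormal edge
  distribution, the mean point density N/Area, and the maximal extent.
* **graph** (25+) — statistics of the radius-neighbour graph (radius =
  the lognormal edge cutoff from the geometric stage) and its minimum
  spanning tree: degrees, components, edge-length statistics, leaf
  counts, the weighted graph diameter ("longest shortest path"),
  path-straightness ratios L_s_ratio / L_l_ratio, and an optional
  Gaussian fit (mu_N, sig_N, W_N) to the per-point local density
  histogram.
* **circularity** (5) — shape ratios of the top-decile density contour
  (blurred 2D histogram, 90th-percentile threshold): isoperimetric
  quotient, contour aspect ratio, radial coefficient of variation,
  solidity, and equivalent-circle radius ratio.
* **symmetry** (7) — quadrant occupancy and extent balance about the
  centre of mass.

Structures are first centred and rotated so the major principal axis
points along x (deterministic sign convention), making every feature
invariant to rigid motions of the input.  Degenerate geometry (collinear
points, empty contours) produces flagged sentinel values instead of
exceptions so batch fingerprinting never aborts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, label as ndi_label
from scipy.sparse.csgraph import connected_components, dijkstra, minimum_spanning_tree
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform
from skimage import measure
from shapely.geometry import Polygon
from sklearn.neighbors import NearestNeighbors, radius_neighbors_graph

__all__ = [
    "Fingerprint",
    "REGISTRY_VERSION",
    "FEATURE_FAMILIES",
    "feature_names",
    "normalize_structure",
    "geometric_features",
    "graph_features",
    "circularity_features",
    "symmetry_features",
    "compute_fingerprint",
    "fingerprints_to_frame",
]

REGISTRY_VERSION = 1

#: versioned feature-name registry, grouped by family
FEATURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "geometric": ("Area", "density", "max_extent"),
    "graph": (
        "graph_n_nodes",
        "graph_n_edges",
        "graph_density",
        "graph_n_components",
        "graph_largest_component_frac",
        "graph_degree_mean",
        "graph_degree_sd",
        "graph_degree_max",
        "graph_degree_min",
        "graph_clustering_mean",
        "graph_edge_len_mean",
        "graph_edge_len_sd",
        "graph_edge_len_max",
        "longest_shortest_path",
        "L_s_ratio",
        "L_l_ratio",
        "mst_total_length",
        "mst_edge_len_mean",
        "mst_edge_len_sd",
        "mst_edge_len_max",
        "mst_leaf_count",
        "mst_leaf_frac",
        "mst_degree_max",
        "mst_depth_mean",
        "mst_depth_sd",
        "mst_diameter",
        "mu_N",
        "sig_N",
        "W_N",
    ),
    "circularity": (
        "circ_isoperimetric",
        "circ_aspect_ratio",
        "circ_radial_cv",
        "circ_solidity",
        "circ_equiv_radius_ratio",
    ),
    "symmetry": (
        "sym_quadrant_ratio",
        "sym_quadrant_entropy",
        "sym_balance_x",
        "sym_balance_y",
        "sym_extent_balance_x",
        "sym_extent_balance_y",
        "sym_diag_contrast",
    ),
    "count": ("N_points",),
}


def feature_names(include_density_fit: bool = True, include_n_points: bool = True):
    names = []
    for family, cols in FEATURE_FAMILIES.items():
        for c in cols:
            if not include_density_fit and c in ("mu_N", "sig_N", "W_N"):
                continue
            if not include_n_points and c == "N_points":
                continue
            names.append(c)
    return names


@dataclass
class Fingerprint:
    """Named feature vector for one assembly, plus degeneracy flags."""

    features: dict[str, float]
    flags: list[str] = field(default_factory=list)
    registry_version: int = REGISTRY_VERSION

    def to_series(self) -> pd.Series:
        return pd.Series(self.features)


# ----------------------------------------------------------------- alignment


def normalize_structure(points: np.ndarray):
    """Centre at the origin and rotate the major principal axis onto x.

    The rotation sign is fixed by requiring a non-negative third moment
    along each axis (falling back to + on perfectly symmetric input), so
    the alignment is deterministic and rigid-motion invariant.  Fewer
    than 3 points switch to minimal mode (centering only).
    Returns ``(aligned_points, flags)``.
    """
    pts = np.asarray(points, float)
    pts = pts - pts.mean(axis=0)
    if len(pts) < 3:
        return pts, ["minimal_mode"]
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]  # major axis first
    rot = evecs[:, order]
    aligned = pts @ rot
    for axis in range(2):
        m3 = np.mean(aligned[:, axis] ** 3)
        if m3 < 0:
            aligned[:, axis] *= -1
    return aligned, []


# ------------------------------------------------------------------ geometric


def _delaunay_edges(pts: np.ndarray):
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
            edges.add((a, b))
    edges = np.array(sorted(edges))
    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    return tri, edges, lengths


def _lognormal_cutoff(lengths: np.ndarray) -> float:
    """95% right-tail cutoff of a log-moment-matched lognormal fit."""
    logs = np.log(lengths[lengths > 0])
    if len(logs) < 10:
        return float(lengths.max())
    mu, sig = logs.mean(), logs.std(ddof=1)
    if sig == 0:
        return float(lengths.max())
    return float(np.exp(mu + 1.6448536269514722 * sig))


def geometric_features(points: np.ndarray):
    """(Area, density, max_extent) plus the edge-length cutoff radius.

    Area sums the Delaunay triangles whose edges all survive lognormal
    right-tail pruning; density is N_points / Area; max_extent is the
    largest pairwise distance.  Collinear input yields sentinel Area 0
    and flagged NaN density.  Returns ``(features, radius, flags)``.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    max_extent = float(pdist(pts).max()) if n >= 2 else 0.0
    try:
        tri, edges, lengths = _delaunay_edges(pts)
    except (QhullError, ValueError):
        feats = {"Area": 0.0, "density": np.nan, "max_extent": max_extent}
        return feats, max_extent if max_extent > 0 else 1.0, ["degenerate_geometry"]
    cutoff = _lognormal_cutoff(lengths)
    ok = {tuple(e) for e, ln in zip(map(tuple, edges), lengths) if ln <= cutoff}
    simp = tri.simplices
    a, b, c = pts[simp[:, 0]], pts[simp[:, 1]], pts[simp[:, 2]]
    u, v = b - a, c - a
    tri_areas = 0.5 * np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    keep = np.array([
        all(tuple(sorted((s[i], s[(i + 1) % 3]))) in ok for i in range(3))
        for s in simp
    ])
    area = float(tri_areas[keep].sum())
    flags = []
    if area == 0:
        flags.append("zero_area")
    feats = {
        "Area": float(area),
        "density": float(n / area) if area > 0 else np.nan,
        "max_extent": max_extent,
    }
    return feats, cutoff, flags


# ---------------------------------------------------------------------- graph


def _double_sweep(adj, src: int, mask=None):
    """Weighted double-sweep Dijkstra: (depths_from_far_node, diameter).

    Exact on trees, a tight lower bound on general graphs.  ``mask``
    restricts to one connected component.
    """
    d0 = dijkstra(adj, directed=False, indices=src)
    d0[~np.isfinite(d0)] = -1.0
    a = int(np.argmax(d0))
    d1 = dijkstra(adj, directed=False, indices=a)
    finite = np.isfinite(d1)
    if mask is not None:
        finite &= mask
    depth = d1[finite]
    return depth, float(depth.max()) if len(depth) else 0.0


def _mean_clustering(adj, rng_seed: int = 0, max_nodes: int = 300) -> float:
    """Mean local clustering coefficient, sampled on large graphs."""
    n = adj.shape[0]
    nodes = np.arange(n)
    if n > max_nodes:
        nodes = np.random.default_rng(rng_seed).choice(n, max_nodes, replace=False)
    csr = adj.tocsr()
    coeffs = []
    for v in nodes:
        nb = csr.indices[csr.indptr[v]:csr.indptr[v + 1]]
        d = len(nb)
        if d < 2:
            coeffs.append(0.0)
            continue
        links = csr[nb][:, nb].nnz / 2
        coeffs.append(2 * links / (d * (d - 1)))
    return float(np.mean(coeffs)) if coeffs else 0.0


def graph_features(points: np.ndarray, radius: float, include_density_fit: bool = True):
    """Radius-neighbour-graph and MST statistics for one structure.

    The weighted diameter ("longest shortest path") uses a double-sweep
    Dijkstra estimate on the largest connected component (exact on
    trees).  L_s_ratio is the shortest weighted path between the two
    max-extent endpoints over the extent; L_l_ratio the (unique) MST path
    between them over the extent.  On a disconnected pair both fall back
    to flagged sentinels.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    flags: list[str] = []
    adj = radius_neighbors_graph(pts, radius=radius, mode="distance")
    adj = adj.tocsr()
    degrees = np.diff(adj.indptr)
    n_edges = adj.nnz // 2
    n_comp, comp_labels = connected_components(adj, directed=False)
    comp_sizes = np.bincount(comp_labels)
    big = int(np.argmax(comp_sizes))
    big_mask = comp_labels == big
    if n_comp > 1:
        flags.append("disconnected_graph")
    edge_w = adj.data if adj.nnz else np.array([0.0])

    src = int(np.flatnonzero(big_mask)[0])
    depth, diameter = _double_sweep(adj, src, big_mask)

    mst = minimum_spanning_tree(adj)  # spanning forest on disconnected graphs
    mst_w = mst.data if mst.nnz else np.array([0.0])
    mst_sym = mst + mst.T
    mst_deg = np.diff(mst_sym.tocsr().indptr)
    leaves = int((mst_deg == 1).sum())
    mst_depth, mst_diam = _double_sweep(mst_sym, src, big_mask)

    # straightness ratios between the two max-extent endpoints; if those
    # fall in different components, use the largest component's own extent
    dmat = squareform(pdist(pts))
    i, j = np.unravel_index(np.argmax(dmat), dmat.shape)
    if not big_mask[i] or not big_mask[j] or not np.isfinite(
        dijkstra(adj, directed=False, indices=int(i))[j]
    ):
        flags.append("extent_endpoints_disconnected")
        sub_idx = np.flatnonzero(big_mask)
        sub_d = dmat[np.ix_(sub_idx, sub_idx)]
        bi, bj = np.unravel_index(np.argmax(sub_d), sub_d.shape)
        i, j = int(sub_idx[bi]), int(sub_idx[bj])
    extent = float(dmat[i, j])
    if extent > 0:
        ls = float(dijkstra(adj, directed=False, indices=int(i))[j]) / extent
        ll = float(dijkstra(mst_sym, directed=False, indices=int(i))[j]) / extent
    else:
        ls = ll = np.nan
        flags.append("degenerate_extent")

    feats = {
        "graph_n_nodes": float(n),
        "graph_n_edges": float(n_edges),
        "graph_density": float(2 * n_edges / (n * (n - 1))) if n > 1 else 0.0,
        "graph_n_components": float(n_comp),
        "graph_largest_component_frac": float(comp_sizes[big] / n),
        "graph_degree_mean": float(degrees.mean()),
        "graph_degree_sd": float(degrees.std()),
        "graph_degree_max": float(degrees.max()),
        "graph_degree_min": float(degrees.min()),
        "graph_clustering_mean": _mean_clustering(adj) if n > 2 else 0.0,
        "graph_edge_len_mean": float(edge_w.mean()),
        "graph_edge_len_sd": float(edge_w.std()),
        "graph_edge_len_max": float(edge_w.max()),
        "longest_shortest_path": diameter,
        "L_s_ratio": ls,
        "L_l_ratio": ll,
        "mst_total_length": float(mst_w.sum()),
        "mst_edge_len_mean": float(mst_w.mean()),
        "mst_edge_len_sd": float(mst_w.std()),
        "mst_edge_len_max": float(mst_w.max()),
        "mst_leaf_count": float(leaves),
        "mst_leaf_frac": float(leaves / n),
        "mst_degree_max": float(mst_deg.max()),
        "mst_depth_mean": float(mst_depth.mean()) if len(mst_depth) else 0.0,
        "mst_depth_sd": float(mst_depth.std()) if len(mst_depth) else 0.0,
        "mst_diameter": mst_diam,
    }
    if include_density_fit:
        feats.update(_density_gaussian_fit(pts))
    return feats, flags


def _density_gaussian_fit(pts: np.ndarray, k: int = 5, bins: int = 20):
    """Gaussian fit (mu_N, sig_N, W_N) to the per-point local density histogram."""
    k = min(k, len(pts) - 1)
    if k < 1:
        return {"mu_N": np.nan, "sig_N": np.nan, "W_N": np.nan}
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
    dist, _ = nn.kneighbors(pts)
    dens = k / (np.pi * np.maximum(dist[:, k], 1e-12) ** 2)
    counts, edges = np.histogram(dens, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts / counts.sum()
    mu = float(w @ centers)
    sig = float(np.sqrt(w @ (centers - mu) ** 2))
    return {"mu_N": mu, "sig_N": sig, "W_N": float(counts.max() / counts.sum())}


# ---------------------------------------------------------------- circularity


def density_mass_threshold(blurred: np.ndarray, mass_fraction: float = 0.9) -> float:
    """Largest threshold whose above-threshold bins hold ``mass_fraction``
    of the total density — the top-density region containing 90% of the
    localizations by default."""
    v = np.sort(blurred.ravel())[::-1]
    cum = np.cumsum(v)
    k = int(np.searchsorted(cum, mass_fraction * cum[-1]))
    return float(v[min(k, len(v) - 1)])


def _contour_polygon(pts: np.ndarray, bins: int = 64, sigma: float = 2.0,
                     mass_fraction: float = 0.9):
    hist, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins)
    blurred = gaussian_filter(hist, sigma=sigma)
    thr = density_mass_threshold(blurred, mass_fraction)
    mask = blurred > thr
    if not mask.any():
        return None
    comp, n_comp = ndi_label(mask)
    sizes = np.bincount(comp.ravel())[1:]
    keep = int(np.argmax(sizes) + 1)
    field = np.where(comp == keep, blurred, 0.0)
    # zero border so the contour closes even when the mask touches the edge
    field = np.pad(field, 1)
    contours = measure.find_contours(field, thr)
    if not contours:
        return None
    contour = max(contours, key=len) - 1.0
    # bin indices -> data units
    dx = xe[1] - xe[0]
    dy = ye[1] - ye[0]
    coords = np.column_stack([xe[0] + contour[:, 0] * dx, ye[0] + contour[:, 1] * dy])
    poly = Polygon(coords)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty or poly.area == 0:
        return None
    # one-bin simplification removes marching-squares pixel jitter, which
    # would otherwise inflate the perimeter of every contour
    simplified = poly.simplify(max(dx, dy))
    if simplified.is_valid and not simplified.is_empty and simplified.area > 0:
        poly = simplified
    return poly


def circularity_features(points: np.ndarray, bins: int = 64, sigma: float = 2.0,
                         mass_fraction: float = 0.9):
    """Five scale-free shape ratios of the top-density contour.

    The contour bounds the highest-density region holding 90% of the
    localizations (blurred 2D histogram, mass threshold).  Structures
    with fewer than 10 points (or a pathological histogram) fall back to
    the convex hull as the contour, flagged.
    """
    pts = np.asarray(points, float)
    flags: list[str] = []
    poly = None
    if len(pts) >= 10:
        poly = _contour_polygon(pts, bins, sigma, mass_fraction)
    if poly is None:
        flags.append("circularity_fallback")
        try:
            hull = ConvexHull(pts)
            poly = Polygon(pts[hull.vertices])
        except (QhullError, ValueError):
            sent = {c: np.nan for c in FEATURE_FAMILIES["circularity"]}
            return sent, flags + ["degenerate_contour"]
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    coords = np.asarray(poly.exterior.coords)
    centroid = coords.mean(axis=0)
    radial = np.linalg.norm(coords - centroid, axis=1)
    cov = np.cov((coords - centroid).T)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    aspect = float(np.sqrt(evals[0] / evals[1])) if evals[1] > 0 else np.inf
    area, perim = poly.area, poly.length
    r_eq = np.sqrt(area / np.pi)
    feats = {
        "circ_isoperimetric": float(4 * np.pi * area / perim**2) if perim > 0 else np.nan,
        "circ_aspect_ratio": aspect,
        "circ_radial_cv": float(radial.std() / radial.mean()) if radial.mean() > 0 else np.nan,
        "circ_solidity": float(area / poly.convex_hull.area) if poly.convex_hull.area > 0 else np.nan,
        "circ_equiv_radius_ratio": float(r_eq / radial.mean()) if radial.mean() > 0 else np.nan,
    }
    return feats, flags


# ------------------------------------------------------------------- symmetry


def symmetry_features(points: np.ndarray):
    """Seven quadrant-occupancy and extent-balance scalars about the origin.

    All features use absolute contrasts, so mirroring the structure
    leaves them unchanged.
    """
    pts = np.asarray(points, float)
    pts = pts - pts.mean(axis=0)
    n = len(pts)
    x, y = pts[:, 0], pts[:, 1]
    q = np.array(
        [
            int(((x >= 0) & (y >= 0)).sum()),
            int(((x < 0) & (y >= 0)).sum()),
            int(((x < 0) & (y < 0)).sum()),
            int(((x >= 0) & (y < 0)).sum()),
        ]
    )
    f = q / n
    nz = f[f > 0]
    entropy = float(-(nz * np.log(nz)).sum() / np.log(4))
    feats = {
        "sym_quadrant_ratio": float((q.max() + 1) / (q.min() + 1)),
        "sym_quadrant_entropy": entropy,
        "sym_balance_x": float(abs((x < 0).sum() - (x >= 0).sum()) / n),
        "sym_balance_y": float(abs((y < 0).sum() - (y >= 0).sum()) / n),
        "sym_extent_balance_x": _extent_balance(x),
        "sym_extent_balance_y": _extent_balance(y),
        "sym_diag_contrast": float(abs(f[0] + f[2] - f[1] - f[3])),
    }
    return feats, []


def _extent_balance(v: np.ndarray) -> float:
    lo, hi = abs(float(v.min())), abs(float(v.max()))
    if max(lo, hi) == 0:
        return 1.0
    return min(lo, hi) / max(lo, hi)


# --------------------------------------------------------------- orchestration


def compute_fingerprint(
    points,
    include_density_fit: bool = True,
    include_n_points: bool = True,
    max_points: int | None = None,
    rng: np.random.Generator | None = None,
) -> Fingerprint:
    """Full fingerprint of one assembly's (x, y) point set.

    ``include_density_fit`` toggles the density-histogram Gaussian
    triplet (mu_N, sig_N, W_N); ``include_n_points`` toggles N_points
    (excluded in the sparse recipe).  ``max_points`` optionally
    subsamples very large assemblies (seeded) before feature extraction.
    Requires at least 4 points.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of x, y")
    if len(pts) < 4:
        raise ValueError(f"fingerprinting needs at least 4 points, got {len(pts)}")
    n_original = len(pts)
    flags: list[str] = []
    if max_points is not None and len(pts) > max_points:
        rng = rng or np.random.default_rng(0)
        pts = pts[rng.choice(len(pts), max_points, replace=False)]
        flags.append("subsampled")
    aligned, f0 = normalize_structure(pts)
    geo, radius, f1 = geometric_features(aligned)
    graph, f2 = graph_features(aligned, radius, include_density_fit)
    circ, f3 = circularity_features(aligned)
    sym, f4 = symmetry_features(aligned)
    features = {**geo, **graph, **circ, **sym}
    if include_n_points:
        features["N_points"] = float(n_original)
    order = feature_names(include_density_fit, include_n_points)
    features = {k: features[k] for k in order}
    return Fingerprint(features=features, flags=flags + f0 + f1 + f2 + f3 + f4)


def fingerprints_to_frame(fingerprints, ids=None) -> pd.DataFrame:
    """Stack fingerprints into one DataFrame (rows = assemblies)."""
    df = pd.DataFrame([fp.features for fp in fingerprints])
    if ids is not None:
        df.insert(0, "assembly_id", list(ids))
    return df
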