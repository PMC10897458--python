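"""Downstream fingerprint analytics.

Fingerprints are standardized, embedded into 2–3 dimensions with UMAP
(a visualization / grouping aid, not part of the fingerprint itself),
grouped with DBSCAN, and optionally explained by feature ranking.  For
ring- or disc-like assemblies the interior Area feature converts to an
equivalent circle radius r = sqrt(A / pi); a Gaussian maximum-likelihood
fit of the per-assembly radii gives the group mean diameter d = 2 mu_r
with error-propagated sigma_d = sqrt(4 sigma_r^2) = 2 sigma_r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

__all__ = [
    "RECIPES",
    "QuantificationResult",
    "embed_fingerprints",
    "group_embedded",
    "rank_features",
    "quantify_radius",
]

#: published analysis presets.  The insulin grouping eps appears both as 1.0
#: and 0.7 in different places; both are shipped, neither is canonical.
RECIPES: dict[str, dict] = {
    "generic": {"n_components": 3, "n_neighbors": 5, "min_dist": 0.1,
                "eps": 0.8, "min_samples": 5, "feature_subset": None,
                "include_density_fit": True},
    "insulin_methods": {"n_components": 2, "n_neighbors": 10, "min_dist": 0.1,
                        "eps": 0.7, "min_samples": 5,
                        "feature_subset": "circularity+straightness",
                        "include_density_fit": True},
    "insulin_results": {"n_components": 2, "n_neighbors": 10, "min_dist": 0.1,
                        "eps": 1.0, "min_samples": 5,
                        "feature_subset": "circularity+straightness",
                        "include_density_fit": True},
    "npc": {"n_components": 3, "n_neighbors": 10, "min_dist": 0.2,
            "eps": 0.8, "min_samples": 5, "feature_subset": None,
            "include_density_fit": False},
}


@dataclass
class QuantificationResult:
    """Equivalent-circle radii and Gaussian-ML diameter summary (nm)."""

    radii: np.ndarray
    mu_r: float
    sigma_r: float

    @property
    def diameter(self) -> float:
        return 2 * self.mu_r

    @property
    def sigma_d(self) -> float:
        return float(np.sqrt(4 * self.sigma_r**2))

    @property
    def n(self) -> int:
        return len(self.radii)


def _subset_columns(columns, subset):
    if subset is None:
        return list(columns)
    if subset == "circularity+straightness":
        keep = [c for c in columns if c.startswith("circ_")]
        keep += [c for c in ("L_s_ratio", "L_l_ratio") if c in columns]
        return keep
    raise ValueError(f"unknown feature subset {subset!r}")


def embed_fingerprints(
    fingerprints: pd.DataFrame,
    n_components: int = 3,
    n_neighbors: int = 5,
    min_dist: float = 0.1,
    seed: int = 0,
    feature_subset: str | None = None,
) -> np.ndarray:
    """Standardize fingerprint features and embed them with seeded UMAP.

    Non-finite entries (flagged sentinels) are imputed with the column
    median and constant columns dropped before z-scoring.
    """
    import umap  # deferred: heavy import

    cols = _subset_columns(
        [c for c in fingerprints.columns if c != "assembly_id"], feature_subset
    )
    X = fingerprints[cols].to_numpy(float)
    if len(X) <= n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={n_neighbors} fingerprints, got {len(X)}"
        )
    med = np.nanmedian(X, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    bad = ~np.isfinite(X)
    X[bad] = np.take(med, np.nonzero(bad)[1])
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=n_components,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
        )
        return reducer.fit_transform(X)


def group_embedded(coordinates: np.ndarray, eps: float = 0.8, min_samples: int = 5):
    """DBSCAN grouping of embedded fingerprints (-1 = unassigned)."""
    coordinates = np.asarray(coordinates, float)
    if len(coordinates) == 0:
        raise ValueError("no coordinates to group")
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(coordinates)
    counts = pd.Series(labels).value_counts().to_dict()
    return labels, counts


def rank_features(
    fingerprints: pd.DataFrame,
    group_labels,
    method: str = "impurity",
    seed: int = 0,
    n_estimators: int = 200,
) -> pd.Series:
    """Per-feature importances for separating fingerprint groups.

    ``impurity`` uses random-forest impurity importances; ``permutation``
    uses permutation importances of the same forest.  Importances are
    normalized to sum to 1 and sorted descending.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance

    labels = np.asarray(group_labels)
    cols = [c for c in fingerprints.columns if c != "assembly_id"]
    X = fingerprints[cols].to_numpy(float)
    X = np.nan_to_num(X, nan=0.0, posinf=0.0, neginf=0.0)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("feature ranking needs at least 2 groups")
    if counts.min() < 5:
        raise ValueError("every group needs at least 5 members")
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    forest.fit(X, labels)
    if method == "impurity":
        imp = forest.feature_importances_
    elif method == "permutation":
        imp = permutation_importance(
            forest, X, labels, n_repeats=5, random_state=seed
        ).importances_mean
        imp = np.clip(imp, 0, None)
    else:
        raise ValueError(f"unknown method {method!r}")
    total = imp.sum()
    imp = imp / total if total > 0 else np.full(len(imp), 1 / len(imp))
    return pd.Series(imp, index=cols).sort_values(ascending=False)


def quantify_radius(areas) -> QuantificationResult:
    """Equivalent-circle radii r = sqrt(A/pi) with a Gaussian ML summary.

    The ML estimates are the sample mean and the ML (ddof=0) standard
    deviation of the radii; diameter d = 2 mu_r, sigma_d = 2 sigma_r.
    """
    areas = np.asarray(areas, float)
    if len(areas) == 0:
        raise ValueError("no areas given")
    if np.any(~np.isfinite(areas)) or np.any(areas <= 0):
        raise ValueError("areas must be positive and finite")
    radii = np.sqrt(areas / np.pi)
    return QuantificationResult(
        radii=radii, mu_r=float(radii.mean()), sigma_r=float(radii.std(ddof=0))
    )
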