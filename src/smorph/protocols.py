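"""Reproducible simulation-study protocols.

These runners bundle the full stress-test workflow — simulate labelled
movies, cluster them with the matching profile, score against ground
truth — plus the downstream morphology-classification study
(fingerprint every extracted assembly, embed, group, score groups
against their majority class).  Both the test suite and the
reproduction script build on them; movie counts are parameters so the
studies scale from desk-size checks to the full 50-movies-per-class
protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import embed_fingerprints, group_embedded
from .clustering import cluster
from .config import load_profile
from .fingerprint import compute_fingerprint, fingerprints_to_frame
from .metrics import onset_offsets, precision_recall_f1, score_clustering
from .simulate import MovieSpec, assemble_movie

log = logging.getLogger(__name__)

#: per-class movie composition and clustering profile of the stress test
STRESS_CLASSES = {
    "isotropic": {"profile": "isotropic", "n_assemblies": {"isotropic": 10}},
    "random": {"profile": "random", "n_assemblies": {"random": 10}},
    "fibril": {"profile": "fibril", "n_assemblies": {"fibril": 25}},
}


@dataclass
class SuiteResult:
    """Scores and artefacts of one class's stress suite."""

    klass: str
    accuracies: np.ndarray  # per-assembly Eq.-style accuracies, pooled
    macro_f1: float  # macro over all assemblies of the suite
    onsets: np.ndarray  # matched |predicted - true| onset offsets [frames]
    n_true: int
    n_extracted: int
    clusters: list = field(default_factory=list)  # (points, majority_class)


def run_stress_suite(
    klass: str,
    n_movies: int,
    seed: int,
    keep_clusters: bool = False,
    **profile_overrides,
) -> SuiteResult:
    """Simulate and score ``n_movies`` movies of one morphology class."""
    cfg = STRESS_CLASSES[klass]
    config = load_profile(cfg["profile"], **profile_overrides)
    accs, tps, fps, fns, onsets = [], [], [], [], []
    n_extracted = 0
    n_true = 0
    clusters = []
    for i in range(n_movies):
        movie = assemble_movie(MovieSpec(n_assemblies=cfg["n_assemblies"],
                                         seed=seed + i))
        result = cluster(movie.table[["x", "y", "t"]], config)
        truth = movie.table["assembly_id"].to_numpy()
        report = score_clustering(result.labels, truth)
        accs.extend(report.per_assembly["accuracy"])
        tps.extend(report.per_assembly["tp"])
        fps.extend(report.per_assembly["fp"])
        fns.extend(report.per_assembly["fn"])
        off = onset_offsets(result.labels, movie.table, movie.ground_truth)
        onsets.extend(off["offset"].dropna())
        n_extracted += result.n_clusters
        n_true += len(movie.ground_truth)
        if keep_clusters:
            for lab in range(result.n_clusters):
                mask = result.labels == lab
                if mask.sum() < 4:
                    continue
                member_truth = truth[mask]
                majority = (
                    klass
                    if (member_truth != -1).sum() > (member_truth == -1).sum()
                    else "noise"
                )
                clusters.append(
                    (movie.table.loc[mask, ["x", "y"]].to_numpy(), majority)
                )
        log.info("%s movie %d: %d clusters", klass, i, result.n_clusters)
    _, _, macro_f1, _ = precision_recall_f1(tps, fps, fns, "macro")
    return SuiteResult(
        klass=klass,
        accuracies=np.asarray(accs, float),
        macro_f1=float(macro_f1),
        onsets=np.asarray(onsets, float),
        n_true=n_true,
        n_extracted=n_extracted,
        clusters=clusters,
    )


def classify_morphologies(
    suites: dict[str, SuiteResult],
    seed: int = 0,
    max_points: int = 1500,
    eps: float = 0.8,
    min_samples: int = 5,
) -> dict:
    """Fingerprint every extracted assembly, embed, group, and score.

    Each extracted cluster is fingerprinted, the fingerprints embedded
    with a 3-component UMAP (n_neighbors 5, min_dist 0.1) and grouped by
    DBSCAN.  Groups whose majority ground-truth class is background noise
    are discarded; every other cluster is predicted to be its group's
    majority class.  Returns per-class F1 and their average (%).
    """
    fps, truths = [], []
    rng = np.random.default_rng(seed)
    for suite in suites.values():
        for pts, majority in suite.clusters:
            fps.append(compute_fingerprint(pts, max_points=max_points, rng=rng))
            truths.append(majority)
    frame = fingerprints_to_frame(fps)
    truths = np.asarray(truths)
    coords = embed_fingerprints(frame, n_components=3, n_neighbors=5,
                                min_dist=0.1, seed=seed)
    groups, _ = group_embedded(coords, eps=eps, min_samples=min_samples)
    predicted = np.array(["unassigned"] * len(truths), dtype=object)
    noise_groups = 0
    for g in np.unique(groups):
        members = groups == g
        vals, counts = np.unique(truths[members], return_counts=True)
        majority = vals[np.argmax(counts)]
        if majority == "noise":
            noise_groups += 1
        predicted[members] = majority
    classes = [c for c in np.unique(truths) if c != "noise"]
    keep = (predicted != "noise") & (truths != "noise")
    f1s = {}
    for c in classes:
        tp = int(((predicted == c) & (truths == c) & keep).sum())
        fp = int(((predicted == c) & (truths != c) & keep).sum())
        fn = int(((predicted != c) & (truths == c) & keep).sum())
        _, _, f1, _ = precision_recall_f1([tp], [fp], [fn], "micro")
        f1s[c] = float(f1)
    return {
        "per_class_f1": f1s,
        "average_f1": float(np.mean(list(f1s.values()))),
        "n_fingerprints": len(fps),
        "n_noise_groups": noise_groups,
    }


def run_sparse_suite(n_movies: int, seed: int, n_points: int = 4) -> dict:
    """Sparse nanostructure recovery: 15 short fibrils + 15 ellipses per
    movie in a 3 µm ROI, clustered with the matching sparse profile."""
    profile = f"sparse-{n_points}"
    config = load_profile(profile)
    accs = []
    for i in range(n_movies):
        spec = MovieSpec(
            fov=(3000.0, 3000.0),
            n_assemblies={"sparse_fibril": 15, "ellipse": 15},
            start_window=300, min_lifetime=50,
            sparse_n_points=n_points, seed=seed + i,
        )
        movie = assemble_movie(spec)
        result = cluster(movie.table[["x", "y", "t"]], config)
        report = score_clustering(
            result.labels, movie.table["assembly_id"].to_numpy()
        )
        accs.extend(report.per_assembly["accuracy"])
    return {"mean_accuracy": float(np.mean(accs)), "n_structures": len(accs)}
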