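"""Ground-truth scoring of clustering output.

Scoring is localization-wise, per ground-truth assembly: each assembly is
matched to the predicted cluster sharing most of its points, then

* TP — the assembly's points inside its matched cluster,
* FN — the assembly's points predicted as noise,
* FP — the assembly's points assigned to any *other* predicted cluster,

giving Accuracy = TP / (TP + FP + FN) per assembly (there is no
meaningful TN at the assembly level).  Precision, recall and F1 follow
the usual definitions and can be aggregated micro (pooled counts), macro
(mean over assemblies) or weighted (TP-weighted mean); macro is the
headline aggregation, avoiding bias toward large assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricsReport",
    "match_clusters",
    "aggregate_accuracy",
    "precision_recall_f1",
    "onset_offsets",
    "score_clustering",
]

NOISE = -1


@dataclass
class MetricsReport:
    """Per-assembly counts and aggregated metrics for one scored movie."""

    per_assembly: pd.DataFrame  # true_id, matched_pred, tp, fp, fn, accuracy
    precision: dict = field(default_factory=dict)  # keyed micro/macro/weighted
    recall: dict = field(default_factory=dict)
    f1: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def accuracies(self) -> np.ndarray:
        return self.per_assembly["accuracy"].to_numpy()

    def summary(self) -> dict:
        return {
            "n_assemblies": int(len(self.per_assembly)),
            "accuracy_mean": float(np.mean(self.accuracies)) if len(self.per_assembly) else np.nan,
            "accuracy_median": float(np.median(self.accuracies)) if len(self.per_assembly) else np.nan,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def match_clusters(pred_labels, true_labels) -> pd.DataFrame:
    """Match each ground-truth assembly to one predicted cluster.

    Greedy one-to-one matching by descending point overlap (ties broken
    by smaller predicted id), then per-assembly TP/FP/FN counts.  Noise
    is ``-1`` on both sides; points correctly predicted as noise
    contribute to no count.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError(f"label vectors differ in length: {pred.shape} vs {true.shape}")
    true_ids = [t for t in np.unique(true) if t != NOISE]
    # overlap counts between every (true, pred-cluster) pair
    overlaps = {}
    for t in true_ids:
        members = pred[true == t]
        ids, counts = np.unique(members[members != NOISE], return_counts=True)
        for p, c in zip(ids, counts):
            overlaps[(t, p)] = int(c)
    # greedy one-to-one: best overlaps first, smaller pred id on ties
    order = sorted(overlaps.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    matched_t, used_p, match = set(), set(), {}
    for (t, p), _ in order:
        if t in matched_t or p in used_p:
            continue
        match[t] = p
        matched_t.add(t)
        used_p.add(p)
    rows = []
    for t in true_ids:
        mask = true == t
        n = int(mask.sum())
        p = match.get(t)
        tp = overlaps.get((t, p), 0) if p is not None else 0
        fn = int((pred[mask] == NOISE).sum())
        fp = n - tp - fn
        rows.append(
            {
                "true_id": t,
                "matched_pred": NOISE if p is None else int(p),
                "n_points": n,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "accuracy": aggregate_accuracy(tp, fp, fn) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def aggregate_accuracy(tp: int, fp: int, fn: int) -> float:
    """Accuracy = TP / (TP + FP + FN); undefined when all counts are zero."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    denom = tp + fp + fn
    if denom == 0:
        raise ValueError("accuracy undefined for TP = FP = FN = 0")
    return tp / denom


def _prf(tp, fp, fn):
    flags = []
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if tp + fp == 0:
        flags.append("precision_undefined")
    if tp + fn == 0:
        flags.append("recall_undefined")
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return precision, recall, f1, flags


def precision_recall_f1(tp, fp, fn, aggregation: str = "macro"):
    """Precision/recall/F1 over per-class count vectors.

    ``aggregation`` is ``micro`` (pool counts), ``macro`` (mean of
    per-class metrics) or ``weighted`` (TP-weighted mean).  Classes with
    undefined denominators score 0 and raise a flag (documented
    convention).  Returns ``(precision, recall, f1, flags)``.
    """
    tp = np.atleast_1d(np.asarray(tp, float))
    fp = np.atleast_1d(np.asarray(fp, float))
    fn = np.atleast_1d(np.asarray(fn, float))
    if aggregation == "micro":
        return _prf(tp.sum(), fp.sum(), fn.sum())
    per = [_prf(a, b, c) for a, b, c in zip(tp, fp, fn)]
    p = np.array([x[0] for x in per])
    r = np.array([x[1] for x in per])
    f = np.array([x[2] for x in per])
    flags = [fl for x in per for fl in x[3]]
    if aggregation == "macro":
        return float(p.mean()), float(r.mean()), float(f.mean()), flags
    if aggregation == "weighted":
        w = tp / tp.sum() if tp.sum() else np.full(len(tp), 1 / len(tp))
        return float(p @ w), float(r @ w), float(f @ w), flags
    raise ValueError(f"unknown aggregation {aggregation!r}")


def score_clustering(pred_labels, true_labels) -> MetricsReport:
    """Full report: per-assembly counts plus micro/macro/weighted metrics."""
    per = match_clusters(pred_labels, true_labels)
    report = MetricsReport(per_assembly=per)
    for agg in ("micro", "macro", "weighted"):
        p, r, f, flags = precision_recall_f1(
            per["tp"].to_numpy(), per["fp"].to_numpy(), per["fn"].to_numpy(), agg
        )
        report.precision[agg] = p
        report.recall[agg] = r
        report.f1[agg] = f
        report.flags.extend(f"{agg}:{fl}" for fl in flags)
    return report


def onset_offsets(
    pred_labels, table: pd.DataFrame, ground_truth: pd.DataFrame
) -> pd.DataFrame:
    """|predicted onset − true onset| per matched assembly, in frames.

    The predicted onset of a matched cluster is the earliest frame among
    its member localizations.  Unmatched assemblies are excluded and
    counted via the ``matched`` column.
    """
    if "t" not in table.columns:
        raise ValueError("onset offsets require a time axis")
    per = match_clusters(pred_labels, table["assembly_id"].to_numpy())
    pred = np.asarray(pred_labels)
    t = table["t"].to_numpy()
    rows = []
    for _, row in per.iterrows():
        gt = ground_truth.loc[ground_truth["assembly_id"] == row["true_id"]]
        true_onset = int(gt["onset"].iloc[0])
        matched = row["matched_pred"] != NOISE
        offset = np.nan
        if matched:
            offset = abs(int(t[pred == row["matched_pred"]].min()) - true_onset)
        rows.append(
            {
                "true_id": row["true_id"],
                "matched": bool(matched),
                "true_onset": true_onset,
                "offset": offset,
            }
        )
    return pd.DataFrame(rows)
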