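"""Evaluation metrics: weighted P/R/F1 over labels, group accuracies, PDSA.

Two complementary views of the same predictions are reported:

* **per-label**: each of the binary labels is scored at a 0.5 threshold on
  the sigmoid outputs, and precision/recall/F1 are support-weighted across
  labels (the label frequencies are imbalanced, so an unweighted macro
  average would over-represent rare labels);
* **per-sample**: scores are decoded to a (plant, disease, severity) triple
  and accuracy is computed per group plus jointly — the plant-disease-
  severity accuracy (PDSA), the fraction of images whose whole triple is
  right.  PDSA can never exceed any single group accuracy.

A sample whose true severity is Healthy carries no disease label; it counts
as disease-correct exactly when the predicted severity is Healthy too.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .label_space import HEALTHY, LabelSpace, TripleLabel, decode_scores

__all__ = [
    "MetricsReport",
    "binary_prf",
    "weighted_prf",
    "group_accuracy",
    "pdsa",
    "per_class_accuracy",
    "evaluate_predictions",
]

GROUPS = ("plant", "disease", "severity")


def binary_prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from confusion counts; 0 on empty denominators."""
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def weighted_prf(scores: np.ndarray, targets: np.ndarray,
                 threshold: float = 0.5) -> tuple[float, float, float]:
    """Support-weighted P/R/F1 over label columns (weights = positive counts)."""
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(targets)
    if scores.shape != targets.shape or scores.ndim != 2:
        raise ValueError(f"scores {scores.shape} and targets {targets.shape} "
                         "must be matching N×L matrices")
    pred = scores >= threshold
    pos = targets == 1
    tp = (pred & pos).sum(axis=0)
    fp = (pred & ~pos).sum(axis=0)
    fn = (~pred & pos).sum(axis=0)
    support = pos.sum(axis=0).astype(float)
    if support.sum() == 0:
        return 0.0, 0.0, 0.0
    ps, rs, fs = zip(*(binary_prf(int(t), int(f), int(n))
                       for t, f, n in zip(tp, fp, fn)))
    w = support / support.sum()
    return float(w @ ps), float(w @ rs), float(w @ fs)


def _component(triple: TripleLabel, group: str):
    if group == "plant":
        return triple.plant
    if group == "severity":
        return triple.severity
    if group == "disease":
        # healthy-gated: a healthy truth is matched by any healthy prediction
        return triple.disease if triple.severity != HEALTHY else None
    raise ValueError(f"unknown group {group!r}")


def _check_pairs(pred_triples, true_triples):
    if len(pred_triples) != len(true_triples):
        raise ValueError("prediction and truth lists differ in length")
    if not true_triples:
        raise ValueError("empty prediction lists")


def group_accuracy(pred_triples, true_triples, group: str) -> float:
    """Percentage of samples whose `group` component is predicted correctly."""
    _check_pairs(pred_triples, true_triples)
    hits = sum(_component(p, group) == _component(t, group)
               for p, t in zip(pred_triples, true_triples))
    return 100.0 * hits / len(true_triples)


def pdsa(pred_triples, true_triples) -> float:
    """Plant-disease-severity accuracy: % of fully correct triples."""
    _check_pairs(pred_triples, true_triples)
    hits = sum(p == t for p, t in zip(pred_triples, true_triples))
    return 100.0 * hits / len(true_triples)


def per_class_accuracy(pred_triples, true_triples, group: str) -> dict:
    """Recall-style accuracy per true class of one group (% per class name)."""
    _check_pairs(pred_triples, true_triples)
    totals: dict = {}
    hits: dict = {}
    for p, t in zip(pred_triples, true_triples):
        name = _component(t, group)
        if name is None:  # healthy samples have no disease class
            continue
        totals[name] = totals.get(name, 0) + 1
        if _component(p, group) == name:
            hits[name] = hits.get(name, 0) + 1
    return {name: 100.0 * hits.get(name, 0) / n for name, n in totals.items()}


@dataclass
class MetricsReport:
    """All evaluation numbers for one prediction set (percent scale)."""

    precision: float
    recall: float
    f1: float
    plant_accuracy: float
    disease_accuracy: float
    severity_accuracy: float
    pdsa: float
    per_class: dict  # group -> {class name -> %}

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "plant_accuracy": self.plant_accuracy,
            "disease_accuracy": self.disease_accuracy,
            "severity_accuracy": self.severity_accuracy,
            "pdsa": self.pdsa,
            "per_class": self.per_class,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def per_class_to_csv(self, group: str, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["name", "accuracy"])
            for name, acc in self.per_class[group].items():
                writer.writerow([name, f"{acc:.2f}"])


def evaluate_predictions(space: LabelSpace, scores: np.ndarray,
                         targets: np.ndarray, true_triples,
                         threshold: float = 0.5) -> MetricsReport:
    """Build a full report from score/target matrices and true triples."""
    scores = np.asarray(scores, dtype=float)
    p, r, f1 = weighted_prf(scores, targets, threshold)
    pred_triples = [decode_scores(space, row) for row in scores]
    return MetricsReport(
        precision=100.0 * p,
        recall=100.0 * r,
        f1=100.0 * f1,
        plant_accuracy=group_accuracy(pred_triples, true_triples, "plant"),
        disease_accuracy=group_accuracy(pred_triples, true_triples, "disease"),
        severity_accuracy=group_accuracy(pred_triples, true_triples, "severity"),
        pdsa=pdsa(pred_triples, true_triples),
        per_class={g: per_class_accuracy(pred_triples, true_triples, g)
                   for g in GROUPS},
    )
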