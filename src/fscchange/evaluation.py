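"""Accuracy metrics, change-detection accounting, and spatial clustering.

Classification accuracy follows the usual confusion-matrix definitions:
overall accuracy OA = trace/N, per-class one-vs-rest precision TP/(TP+FP)
and recall TP/(TP+FN), F1 as their harmonic mean, and Cohen's kappa
κ = (P₀ − Pₑ)/(1 − Pₑ) with P₀ the observed agreement and Pₑ the chance
agreement Σ row_marginal·col_marginal / N².  The task has five classes, so
the single reported precision/recall/F1 are unweighted macro averages
(weighted averaging is available as an option).

Spatial clustering of detected changes is quantified by the Clark–Evans
nearest-neighbor index NNI = d̄_obs / d̄_exp with d̄_exp = 0.5/√(n/A) under
complete spatial randomness, z = (d̄_obs − d̄_exp)/SE, SE = 0.26136/√(n²/A),
and a two-sided normal p-value; no edge correction is applied.  NNI < 1
indicates clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import norm

from .exceptions import DegenerateInputError, FormatError


@dataclass
class ConfusionMatrix:
    """Counts with rows = reference labels, columns = predicted labels."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricReport:
    OA: float
    precision: float
    recall: float
    F1: float
    kappa: float
    averaging: str
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "OA": self.OA, "precision": self.precision, "recall": self.recall,
            "F1": self.F1, "kappa": self.kappa, "averaging": self.averaging,
            "per_class": self.per_class,
        }


@dataclass
class PointPattern:
    """Planar points (meters) in a study area of known extent."""

    points: np.ndarray  # (n, 2)
    area: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 2:
            raise DegenerateInputError("point pattern needs at least 2 points")
        if self.area <= 0:
            raise DegenerateInputError("study area must be positive")


def confusion(reference, predicted, class_order: tuple[str, ...] | None = None) -> ConfusionMatrix:
    """Confusion counts; ``counts[a, b]`` = #(reference=a, predicted=b)."""
    reference = list(reference)
    predicted = list(predicted)
    if len(reference) != len(predicted):
        raise FormatError("reference and predicted label lists differ in length")
    if not reference:
        raise FormatError("empty label lists")
    if class_order is None:
        class_order = tuple(sorted(set(reference) | set(predicted)))
    index = {c: k for k, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for r, p in zip(reference, predicted):
        counts[index[r], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=class_order)


def metrics(cm: ConfusionMatrix, averaging: str = "macro") -> MetricReport:
    """OA, macro (or weighted) precision/recall/F1, and Cohen's kappa.

    A class never predicted (TP+FP = 0) gets precision 0 with a flag; the
    average still includes it.
    """
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise DegenerateInputError("empty confusion matrix")
    oa = float(np.trace(counts) / total)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    pe = float(np.sum(row * col) / total**2)
    kappa = 0.0 if pe == 1.0 else float((oa - pe) / (1.0 - pe))

    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    precisions, recalls, f1s, weights = [], [], [], []
    for k, cls in enumerate(cm.class_order):
        tp = counts[k, k]
        fp = col[k] - tp
        fn = row[k] - tp
        if tp + fp == 0:
            precision = 0.0
            flags.append(f"class {cls}: never predicted (precision defined as 0)")
        else:
            precision = float(tp / (tp + fp))
        recall = float(tp / (tp + fn)) if (tp + fn) > 0 else 0.0
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        per_class[cls] = {"precision": precision, "recall": recall, "F1": f1}
        precisions.append(precision)
        recalls.append(recall)
        f1s.append(f1)
        weights.append(row[k])
    if averaging == "macro":
        w = np.ones(len(precisions)) / len(precisions)
    elif averaging == "weighted":
        w = np.asarray(weights) / total
    else:
        raise FormatError(f"unknown averaging {averaging!r}")
    return MetricReport(
        OA=oa,
        precision=float(np.dot(w, precisions)),
        recall=float(np.dot(w, recalls)),
        F1=float(np.dot(w, f1s)),
        kappa=kappa,
        averaging=averaging,
        per_class=per_class,
        flags=flags,
    )


def detection_rate(reference_changed: set, detected_changed: set) -> tuple[int, int, float]:
    """(detected, missed, rate) of reference changes found by the algorithm.

    ``detected + missed`` always equals the reference count.
    """
    reference_changed = set(reference_changed)
    if not reference_changed:
        raise DegenerateInputError("empty reference change set")
    detected = len(reference_changed & set(detected_changed))
    missed = len(reference_changed) - detected
    return detected, missed, detected / len(reference_changed)


def nearest_neighbor_index(pattern: PointPattern) -> tuple[float, float, float]:
    """Clark–Evans nearest-neighbor index with CSR z-test.

    Returns ``(NNI, z, p)``; NNI < 1 indicates spatial clustering.  A pattern
    of coincident points has observed distance 0 and hence NNI 0.
    """
    pts = pattern.points
    n = len(pts)
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    d_obs = float(np.mean(dists[:, 1]))
    density = n / pattern.area
    d_exp = 0.5 / np.sqrt(density)
    se = 0.26136 / np.sqrt(n**2 / pattern.area)
    nni = d_obs / d_exp
    z = (d_obs - d_exp) / se
    p = 2.0 * float(norm.sf(abs(z)))
    return float(nni), float(z), p
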