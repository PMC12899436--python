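"""Detection and agreement statistics for comparing segmentation methods.

Object-level detection is scored without true negatives (there is no
meaningful "correctly absent nucleus" in instance detection):

- recall   = TP / (TP + FN)
- precision = TP / (TP + FP)
- F-measure = harmonic mean of precision and recall = Dice on TP/FP/FN
- accuracy = TP / (TP + FP + FN) = Jaccard
- Jaccard  = Dice / (2 − Dice)

Reproducibility across repeated runs is summarised by the sample variance
``VS`` (n−1 denominator) and population variance ``VP`` (n denominator),
whose ratio is identically ``(n−1)/n``; inter-method and inter-channel
consistency by Pearson's r, and inter-rater agreement by Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score


class UndefinedMetricError(ValueError):
    pass


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]]  # (predicted_idx, truth_idx)

    def __post_init__(self) -> None:
        if self.tp != len(self.pairs):
            raise ValueError("tp must equal the number of matched pairs")


@dataclass
class MetricsReport:
    recall: float
    precision: float
    f_measure: float
    accuracy: float
    dice: float
    jaccard: float


@dataclass
class VarianceReport:
    n: int
    vs: float  # sample variance, n-1 denominator
    vp: float  # population variance, n denominator
    ratio: float  # vp / vs == (n-1)/n


@dataclass
class AgreementReport:
    pearson_r: float
    cohens_kappa: float


def match_objects(
    predicted_centroids: Sequence[tuple[float, float]],
    truth_centroids: Sequence[tuple[float, float]],
    *,
    criterion: Literal["centroid", "iou"] = "centroid",
    centroid_radius_px: float = 10.0,
    iou_threshold: float = 0.5,
    predicted_masks: Sequence[np.ndarray] | None = None,
    truth_masks: Sequence[np.ndarray] | None = None,
) -> MatchResult:
    """Greedy one-to-one matching of predicted against true objects.

    With the centroid criterion, pairs within ``centroid_radius_px`` are
    matched nearest-first; with the IoU criterion, pairs with mask IoU at
    least ``iou_threshold`` are matched highest-overlap-first.  Unmatched
    predictions are false positives, unmatched truths false negatives.
    """
    n_pred, n_true = len(predicted_centroids), len(truth_centroids)
    if criterion == "iou":
        if predicted_masks is None or truth_masks is None:
            raise ValueError("IoU criterion requires masks")
        score = np.zeros((n_pred, n_true))
        for i, pm in enumerate(predicted_masks):
            pm = np.asarray(pm, dtype=bool)
            for j, tm in enumerate(truth_masks):
                tm = np.asarray(tm, dtype=bool)
                union = np.logical_or(pm, tm).sum()
                score[i, j] = np.logical_and(pm, tm).sum() / union if union else 0.0
        eligible = score >= iou_threshold
        order_key = -score
    else:
        pred = np.asarray(predicted_centroids, dtype=float).reshape(n_pred, 2)
        true = np.asarray(truth_centroids, dtype=float).reshape(n_true, 2)
        dist = np.linalg.norm(pred[:, None, :] - true[None, :, :], axis=2)
        eligible = dist <= centroid_radius_px
        order_key = dist

    pairs: list[tuple[int, int]] = []
    if n_pred and n_true:
        used_p: set[int] = set()
        used_t: set[int] = set()
        for flat in np.argsort(order_key, axis=None, kind="stable"):
            i, j = np.unravel_index(flat, eligible.shape)
            if not eligible[i, j] or i in used_p or j in used_t:
                continue
            pairs.append((int(i), int(j)))
            used_p.add(int(i))
            used_t.add(int(j))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=n_pred - tp, fn=n_true - tp, pairs=pairs)


def f_measure(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision (F1)."""
    if recall + precision == 0:
        raise UndefinedMetricError("recall + precision is zero")
    return 2.0 * precision * recall / (precision + recall)


def jaccard_from_dice(dice: float) -> float:
    """Dice–Jaccard bijection J = D / (2 − D)."""
    return dice / (2.0 - dice)


def detection_metrics(m: MatchResult) -> MetricsReport:
    """Recall/precision/F/accuracy/Dice/Jaccard from TP, FP, FN counts."""
    if m.tp + m.fn == 0 or m.tp + m.fp == 0:
        raise UndefinedMetricError("no truth objects or no predictions")
    recall = m.tp / (m.tp + m.fn)
    precision = m.tp / (m.tp + m.fp)
    if m.tp == 0:
        raise UndefinedMetricError("no matches; F-measure undefined")
    f = f_measure(recall, precision)
    accuracy = m.tp / (m.tp + m.fp + m.fn)
    return MetricsReport(
        recall=recall,
        precision=precision,
        f_measure=f,
        accuracy=accuracy,
        dice=f,
        jaccard=jaccard_from_dice(f),
    )


def population_variance_from_sample(vs: float, n: int) -> float:
    """VP from VS via the identity VP = VS · (n−1)/n."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return vs * (n - 1) / n


def variance_report(x: Sequence[float]) -> VarianceReport:
    """Sample and population variance of repeated measurements."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("variance_report requires n >= 2")
    vs = float(np.var(x, ddof=1))
    vp = float(np.var(x, ddof=0))
    return VarianceReport(n=int(x.size), vs=vs, vp=vp, ratio=(x.size - 1) / x.size)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("pearson requires two equal-length vectors of n >= 2")
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedMetricError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def correlation_matrix(runs: dict[str, Sequence[float]]) -> "np.ndarray":
    """Pairwise Pearson matrix over named measurement vectors (run-vs-run)."""
    names = list(runs)
    mat = np.eye(len(names))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                mat[i, j] = mat[j, i] = pearson(runs[a], runs[b])
    return mat


def cohens_kappa(a: Sequence, b: Sequence) -> float:
    """Cohen's kappa inter-rater agreement with marginal-product chance level."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size != b.size or a.size < 1:
        raise ValueError("cohens_kappa requires two equal-length label vectors")
    if np.array_equal(a, b):
        return 1.0
    kappa = cohen_kappa_score(a, b)
    if np.isnan(kappa):
        raise UndefinedMetricError("expected agreement is 1; kappa undefined")
    return float(kappa)


def agreement_report(x: Sequence[float], y: Sequence[float], a: Sequence, b: Sequence) -> AgreementReport:
    """Bundle Pearson (counts) and kappa (categorical calls) agreement."""
    return AgreementReport(pearson_r=pearson(x, y), cohens_kappa=cohens_kappa(a, b))
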