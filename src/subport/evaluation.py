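"""Metrics, stratified reports, baselines and significance tests.

Binary classification quality is summarized by accuracy, precision, recall,
Matthews correlation (MCC) and ROC-AUC.  MCC and the confusion-matrix
metrics are computed in closed form from the thresholded confusion matrix;
ROC-AUC is the Mann-Whitney rank statistic with midrank tie correction.
Stratified reports slice a test set by maximum identity to training, by
substrate occurrence in training, or by any categorical annotation (domain
of life, subcellular location, transporter class).  The k-most-similar-
protein baseline predicts the substrate union of a test protein's nearest
training neighbors; McNemar's test compares paired classifiers; and the
screening projection turns a false/true positive rate into expected hit
counts for a candidate-screening experiment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .proteins import IdentityProvider
from .records import InteractionPair, Label, TransporterRecord

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMetrics",
    "binary_metrics",
    "multiclass_mcc",
    "EvaluationReport",
    "stratified_report",
    "confusion_matrix_table",
    "confidence_bins",
    "mcnemar_test",
    "BaselineConfig",
    "similarity_baseline",
    "screening_projection",
]


@dataclass(frozen=True)
class BinaryMetrics:
    accuracy: float
    precision: float
    recall: float
    mcc: float
    roc_auc: float
    n: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "mcc": self.mcc,
            "roc_auc": self.roc_auc,
            "n": self.n,
        }


def _roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC-AUC as the normalized Mann-Whitney U with midrank tie handling."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        logger.warning("ROC-AUC undefined for single-class labels; returning 0")
        return 0.0
    ranks = stats.rankdata(scores)  # average ranks resolve ties
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def binary_metrics(
    labels: Sequence[int] | np.ndarray,
    scores: Sequence[float] | np.ndarray,
    threshold: float = 0.5,
) -> BinaryMetrics:
    """Accuracy, precision, recall, MCC and ROC-AUC at ``score > threshold``.

    Labels must be 0/1.  Degenerate denominators (no predicted positives, a
    single true class, a vanishing MCC denominator) yield metric 0 with a
    warning rather than an error.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(labels) < 1:
        raise ValueError("need at least one element")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    predicted = (scores > threshold).astype(int)
    tp = int(np.sum((predicted == 1) & (labels == 1)))
    tn = int(np.sum((predicted == 0) & (labels == 0)))
    fp = int(np.sum((predicted == 1) & (labels == 0)))
    fn = int(np.sum((predicted == 0) & (labels == 1)))
    n = len(labels)
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    if denom == 0:
        logger.warning("MCC denominator is zero; returning 0")
    return BinaryMetrics(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        mcc=float(mcc),
        roc_auc=_roc_auc(labels, scores),
        n=n,
    )


def multiclass_mcc(labels: np.ndarray, predicted: np.ndarray) -> float:
    """Mean one-vs-rest MCC across the classes present in the truth."""
    values = []
    for cls in np.unique(labels):
        y = (labels == cls).astype(int)
        p = (predicted == cls).astype(float)
        values.append(binary_metrics(y, p).mcc)
    return float(np.mean(values)) if values else 0.0


@dataclass
class EvaluationReport:
    """Overall metrics plus per-stratum metrics for one stratification."""

    overall: BinaryMetrics
    strata: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stratum": "overall", **self.overall.as_dict()}]
        for s in self.strata:
            metrics = s["metrics"].as_dict() if s["metrics"] is not None else {}
            rows.append({"stratum": s["stratum"], "n": s["n"], **metrics})
        return pd.DataFrame(rows)


def _bin_label(value: float, edges: Sequence[float]) -> str:
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo <= value < hi or (hi == edges[-1] and value == hi):
            return f"[{lo:g},{hi:g})" if hi != edges[-1] else f"[{lo:g},{hi:g}]"
    return "out-of-range"


def stratified_report(
    labels: np.ndarray,
    scores: np.ndarray,
    annotations: pd.DataFrame,
    scheme: str,
    bin_edges: Optional[Sequence[float]] = None,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Per-stratum metrics under one stratification scheme.

    ``scheme`` names a column of ``annotations`` (row-aligned with labels
    and scores).  Numeric columns are binned with ``bin_edges``; categorical
    columns stratify by value.  Empty strata report ``n=0`` with null
    metrics; stratum sizes always sum to the overall count.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(annotations) != len(labels):
        raise ValueError("annotations must align with labels/scores")
    if scheme not in annotations.columns:
        raise KeyError(f"annotation column {scheme!r} not found")
    column = annotations[scheme]
    if bin_edges is not None:
        strata_keys = [_bin_label(float(v), bin_edges) for v in column]
        ordered = []
        for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
            ordered.append(
                f"[{lo:g},{hi:g})" if hi != bin_edges[-1] else f"[{lo:g},{hi:g}]"
            )
    else:
        strata_keys = [str(v) for v in column]
        ordered = sorted(set(strata_keys))
    report = EvaluationReport(overall=binary_metrics(labels, scores, threshold))
    keys = np.array(strata_keys)
    for stratum in ordered:
        mask = keys == stratum
        n = int(mask.sum())
        metrics = binary_metrics(labels[mask], scores[mask], threshold) if n else None
        report.strata.append({"stratum": stratum, "n": n, "metrics": metrics})
    return report


def confusion_matrix_table(
    labels: np.ndarray, predicted: np.ndarray, class_names: Sequence[str]
) -> pd.DataFrame:
    """Confusion matrix (rows = actual, columns = predicted) as a DataFrame."""
    k = len(class_names)
    matrix = np.zeros((k, k), dtype=int)
    for a, p in zip(labels, predicted):
        matrix[int(a), int(p)] += 1
    return pd.DataFrame(matrix, index=list(class_names), columns=list(class_names))


def confidence_bins(
    scores: np.ndarray,
    labels: np.ndarray,
    low: float = 0.4,
    high: float = 0.6,
    threshold: float = 0.5,
) -> tuple[float, float, float]:
    """Split predictions into confident (score <low or >high) vs uncertain.

    Returns ``(fraction_confident, accuracy_confident, accuracy_uncertain)``;
    an empty group's accuracy is NaN.
    """
    if low >= high:
        raise ValueError("low must be < high")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    predicted = (scores > threshold).astype(int)
    confident = (scores > high) | (scores < low)
    frac = float(confident.mean()) if len(scores) else 0.0
    correct = predicted == labels

    def acc(mask):
        return float(correct[mask].mean()) if mask.any() else float("nan")

    return frac, acc(confident), acc(~confident)


def mcnemar_test(
    correctness_a: Sequence[int] | np.ndarray,
    correctness_b: Sequence[int] | np.ndarray,
    exact_cutoff: int = 25,
) -> float:
    """McNemar's test on paired 0/1 correctness vectors; returns the p-value.

    Uses the exact two-sided binomial test on the discordant pairs when
    there are fewer than ``exact_cutoff`` of them, otherwise the chi-square
    statistic with continuity correction.  Zero discordant pairs give p=1.
    """
    a = np.asarray(correctness_a).astype(int)
    b = np.asarray(correctness_b).astype(int)
    if a.shape != b.shape:
        raise ValueError("correctness vectors must be paired (equal length)")
    n01 = int(np.sum((a == 1) & (b == 0)))
    n10 = int(np.sum((a == 0) & (b == 1)))
    discordant = n01 + n10
    if discordant == 0:
        return 1.0
    if discordant < exact_cutoff:
        return float(stats.binomtest(min(n01, n10), discordant, 0.5).pvalue)
    statistic = (abs(n01 - n10) - 1) ** 2 / discordant
    return float(stats.chi2.sf(statistic, df=1))


@dataclass(frozen=True)
class BaselineConfig:
    """k = number of most-identical training proteins whose substrates are predicted."""

    k: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def similarity_baseline(
    test_transporters: Sequence[TransporterRecord],
    test_positives: Sequence[InteractionPair],
    train_pairs: Sequence[InteractionPair],
    identities: IdentityProvider,
    config: BaselineConfig = BaselineConfig(),
) -> tuple[dict[str, set[str]], dict[str, float]]:
    """Homology-transfer baseline: predict the substrates of close homologs.

    For each test transporter the predicted substrate set is the union of
    the positive substrates of its ``k`` most identical training proteins
    (ties broken by accession order).  Scoring counts, per test protein,
    TP = predicted AND true, FN = true not predicted, FP = predicted not
    true; aggregates are precision = sum TP/(TP+FP), recall = sum TP/(TP+FN)
    and accuracy = sum TP/(TP+FP+FN) — there is no true-negative notion in
    this set-valued scheme.
    """
    train_substrates: dict[str, set[str]] = {}
    for p in train_pairs:
        if p.label is Label.POSITIVE:
            train_substrates.setdefault(p.transporter_id, set()).add(p.chebi_id)
    if not train_substrates:
        raise ValueError("train set has no positive pairs")
    train_ids = sorted(train_substrates)
    if config.k > len(train_ids):
        raise ValueError(f"k={config.k} exceeds {len(train_ids)} training proteins")
    true_substrates: dict[str, set[str]] = {}
    for p in test_positives:
        if p.label is Label.POSITIVE:
            true_substrates.setdefault(p.transporter_id, set()).add(p.chebi_id)
    predictions: dict[str, set[str]] = {}
    tp = fp = fn = 0
    for rec in test_transporters:
        ranked = sorted(
            train_ids,
            key=lambda t: (-identities.identity(rec.uniprot_id, t), t),
        )
        predicted: set[str] = set()
        for neighbor in ranked[: config.k]:
            predicted |= train_substrates[neighbor]
        predictions[rec.uniprot_id] = predicted
        true = true_substrates.get(rec.uniprot_id, set())
        tp += len(predicted & true)
        fp += len(predicted - true)
        fn += len(true - predicted)
    metrics = {
        "precision": tp / (tp + fp) if (tp + fp) else 0.0,
        "recall": tp / (tp + fn) if (tp + fn) else 0.0,
        "accuracy": tp / (tp + fp + fn) if (tp + fp + fn) else 0.0,
    }
    return predictions, metrics


def screening_projection(
    n_candidates: int, n_true: int, fpr: float, tpr: float
) -> tuple[int, float]:
    """Expected false and true positives when screening a candidate library.

    With ``n_candidates`` compounds of which ``n_true`` are real substrates,
    a classifier with the given false/true positive rates is expected to
    flag ``round(fpr * (n_candidates - n_true))`` non-substrates and
    ``tpr * n_true`` real substrates.
    """
    if not (0 <= n_true <= n_candidates):
        raise ValueError("require 0 <= n_true <= n_candidates")
    for name, rate in (("fpr", fpr), ("tpr", tpr)):
        if not (0 <= rate <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    expected_fp = round(fpr * (n_candidates - n_true))
    expected_tp = tpr * n_true
    return int(expected_fp), float(expected_tp)
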