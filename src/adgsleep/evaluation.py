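"""Staging metrics: confusion matrix, per-class PRF, macro-F1, Cohen's
kappa, bootstrap confidence intervals, and LOSO-fold aggregation.

All metrics are computed from first principles on the 5×5 confusion
matrix (rows = true stage, columns = predicted stage); sklearn's
implementations serve only as independent cross-checks in the test
suite.  Zero-denominator precision/recall cases return 0 and are flagged
rather than propagating NaN into the macro average.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import ConfigurationError, N_STAGES, STAGE_NAMES

logger = logging.getLogger(__name__)


class DataError(ValueError):
    pass


def confusion_matrix(y_true, y_pred, n_classes: int = N_STAGES) -> np.ndarray:
    """Count matrix with entry (i, j) = true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise DataError("empty label arrays")
    if y_true.shape != y_pred.shape:
        raise DataError("label arrays differ in length")
    if (y_true.min() < 0 or y_true.max() >= n_classes
            or y_pred.min() < 0 or y_pred.max() >= n_classes):
        raise DataError(f"labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def per_class_prf(cm: np.ndarray) -> dict[str, np.ndarray]:
    """Precision, recall and F1 per class; degenerate classes give 0."""
    cm = np.asarray(cm)
    diag = np.diag(cm).astype(float)
    colsum = cm.sum(axis=0).astype(float)
    rowsum = cm.sum(axis=1).astype(float)
    flagged = []
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(colsum > 0, diag / colsum, 0.0)
        recall = np.where(rowsum > 0, diag / rowsum, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    for k in range(cm.shape[0]):
        if colsum[k] == 0 or rowsum[k] == 0:
            flagged.append(k)
    if flagged:
        logger.warning("degenerate classes (zero row/col sum): %s", flagged)
    return {"precision": precision, "recall": recall, "f1": f1,
            "flagged": np.asarray(flagged, dtype=int)}


def f1_score_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def macro_f1(f1_values) -> float:
    """Unweighted mean of exactly 5 per-class F1 scores."""
    f1_values = np.asarray(f1_values, dtype=float)
    if f1_values.shape != (N_STAGES,):
        raise ConfigurationError(f"expected {N_STAGES} F1 values, "
                                 f"got {f1_values.shape}")
    return float(f1_values.mean())


def accuracy(cm: np.ndarray) -> float:
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise DataError("empty confusion matrix")
    return float(np.trace(cm) / total)


def cohen_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement κ = (p_o − p_e)/(1 − p_e)."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise DataError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total ** 2
    if p_e >= 1.0:
        return 1.0 if p_o >= 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def bootstrap_ci(y_true, y_pred, metric=None, B: int = 1000,
                 level: float = 0.95, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI for a metric of (true, predicted) pairs.

    Resamples epoch-level pairs with replacement B times.  ``metric``
    takes (y_true, y_pred) and returns a scalar; default is accuracy.
    Replicates on which the metric raises are skipped (count logged).
    """
    if B < 100:
        raise ConfigurationError("B must be >= 100")
    if not 0 < level < 1:
        raise ConfigurationError("level must be in (0, 1)")
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if metric is None:
        metric = lambda t, p: float(np.mean(t == p))
    rng = np.random.default_rng(seed)
    n = len(y_true)
    values, skipped = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(metric(y_true[idx], y_pred[idx]))
        except Exception:
            skipped += 1
    if skipped:
        logger.warning("bootstrap: %d/%d replicates skipped", skipped, B)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class EvalReport:
    """Everything reported for one evaluation (one fold or pooled)."""

    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    macro_f1: float
    kappa: float
    ci: tuple[float, float] | None = None
    ci_level: float = 0.95
    ci_b: int = 1000
    per_fold_accuracy: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"confusion_matrix": self.confusion.tolist(),
             "stages": list(STAGE_NAMES),
             "per_class": {STAGE_NAMES[k]: {"precision": float(self.precision[k]),
                                            "recall": float(self.recall[k]),
                                            "f1": float(self.f1[k])}
                           for k in range(N_STAGES)},
             "accuracy": self.accuracy, "macro_f1": self.macro_f1,
             "kappa": self.kappa}
        if self.ci is not None:
            d["bootstrap_ci"] = {"lower": self.ci[0], "upper": self.ci[1],
                                 "level": self.ci_level, "B": self.ci_b}
        if self.per_fold_accuracy:
            d["per_fold_accuracy"] = self.per_fold_accuracy
        return d

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_predictions(y_true, y_pred, bootstrap: bool = True,
                         B: int = 1000, level: float = 0.95,
                         seed: int = 0) -> EvalReport:
    """Full report from one set of stage predictions."""
    cm = confusion_matrix(y_true, y_pred)
    prf = per_class_prf(cm)
    ci = bootstrap_ci(y_true, y_pred, B=B, level=level, seed=seed) \
        if bootstrap else None
    return EvalReport(cm, prf["precision"], prf["recall"], prf["f1"],
                      accuracy(cm), macro_f1(prf["f1"]), cohen_kappa(cm),
                      ci=ci, ci_level=level, ci_b=B)


def aggregate_folds(reports: list[EvalReport]) -> EvalReport:
    """Average per-fold metrics; also pool confusion matrices.

    The headline numbers are the unweighted means across folds; the
    pooled confusion matrix is kept for transparency and drives the
    pooled per-class PRF columns.
    """
    if not reports:
        raise ConfigurationError("need at least one fold report")
    shapes = {r.confusion.shape for r in reports}
    if len(shapes) != 1:
        raise ConfigurationError("inconsistent class counts across folds")
    pooled = np.sum([r.confusion for r in reports], axis=0)
    prf = per_class_prf(pooled)
    return EvalReport(
        pooled, prf["precision"], prf["recall"], prf["f1"],
        accuracy=float(np.mean([r.accuracy for r in reports])),
        macro_f1=float(np.mean([r.macro_f1 for r in reports])),
        kappa=float(np.mean([r.kappa for r in reports])),
        per_fold_accuracy=[r.accuracy for r in reports])
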