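"""Evaluation metrics for positive-unlabeled (PU) validation.

With no labeled negatives, the classical confusion matrix cannot be filled
in: only TP and FN are countable, so recall r = P[f(x)=1 | Y=1] is the
only directly estimable classical metric.  Precision p = P[Y=1 | f(x)=1]
is instead recovered by Bayes inversion from the three estimable
quantities

    p = r * P[Y=1] / P[f(x)=1],

where P[Y=1] is the class prior (fraction of known positives in the
validation pool) and P[f(x)=1] is the overall positive-prediction rate.
When the classifier's positive-prediction rate equals the prior, p = r —
the "even-break point" behaviour that one-class models trained only on
positives tend to exhibit.

A "naive" mode that treats unlabeled validation items as negatives is also
provided for comparison with binary-classifier conventions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .ocsvm import INLIER

logger = logging.getLogger("ocgene")

#: truth-label code for unlabeled entries (excluded from confusion counts)
UNLABELED = 0


class PUMetricsError(ValueError):
    """Raised when an estimator is undefined for the given inputs."""


@dataclass
class ConfusionCounts:
    """Confusion-matrix counts; fp/tn are None in PU mode (no negatives)."""

    tp: int
    fn: int
    fp: int | None = None
    tn: int | None = None
    degenerate: bool = False


@dataclass
class PUMetrics:
    """PU-estimated evaluation bundle.

    All proportions lie in [0, 1]; ``pu_criterion`` is the model-selection
    statistic r^2 / P[f(x)=1], proportional to p * r.
    """

    recall_hat: float
    positive_rate_hat: float
    class_prior: float
    precision_hat: float
    f_measure: float
    pu_criterion: float

    def as_percent(self) -> dict:
        """Precision/recall/F as percentages rounded to 2 decimals."""
        return {
            "precision": round(100.0 * self.precision_hat, 2),
            "recall": round(100.0 * self.recall_hat, 2),
            "f_measure": round(100.0 * self.f_measure, 2),
        }


def confusion_from_labels(truth: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    """Count confusion-matrix cells, skipping entries with truth UNLABELED.

    If no labeled negatives are present the result is PU-mode: fp and tn
    are None.  truth uses {+1, -1, 0=unlabeled}; pred uses {+1, -1}.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise PUMetricsError(
            f"truth and prediction lengths differ: {truth.shape} vs {pred.shape}"
        )
    labeled = truth != UNLABELED
    if not labeled.any():
        return ConfusionCounts(tp=0, fn=0, fp=None, tn=None, degenerate=True)
    t, p = truth[labeled], pred[labeled]
    tp = int(np.sum((t == 1) & (p == INLIER)))
    fn = int(np.sum((t == 1) & (p != INLIER)))
    has_neg = bool(np.any(t == -1))
    fp = int(np.sum((t == -1) & (p == INLIER))) if has_neg else None
    tn = int(np.sum((t == -1) & (p != INLIER))) if has_neg else None
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def estimate_recall(pred_on_heldout_positives: np.ndarray) -> float:
    """r-hat: fraction of held-out known positives predicted inlier."""
    pred = np.asarray(pred_on_heldout_positives)
    if pred.size == 0:
        raise PUMetricsError("recall estimator undefined on an empty positive set")
    return float(np.mean(pred == INLIER))


def estimate_positive_rate(pred_on_full_validation: np.ndarray) -> float:
    """P[f(x)=1]-hat: fraction of the whole validation pool predicted inlier."""
    pred = np.asarray(pred_on_full_validation)
    if pred.size == 0:
        raise PUMetricsError("positive-rate estimator undefined on an empty validation set")
    return float(np.mean(pred == INLIER))


def estimate_precision(recall_hat: float, class_prior: float, positive_rate_hat: float) -> float:
    """p-hat = r-hat * P[Y=1] / P[f(x)=1], clipped to [0, 1].

    Bayes inversion of the precision definition using the two quantities
    estimable without negatives.  Estimates above 1 (sampling noise) are
    clipped and logged.
    """
    if positive_rate_hat <= 0.0:
        raise PUMetricsError(
            "precision is undefined: the classifier predicted no positives "
            "(positive rate = 0)"
        )
    if not 0.0 < class_prior <= 1.0:
        raise PUMetricsError(f"class prior must lie in (0, 1], got {class_prior}")
    raw = recall_hat * class_prior / positive_rate_hat
    if raw > 1.0:
        logger.info("PU precision estimate %.4f > 1 clipped to 1 (sampling noise)", raw)
    return float(np.clip(raw, 0.0, 1.0))


def f_measure(p: float, r: float) -> float:
    """Harmonic mean 2pr/(p+r); 0 when both are 0."""
    if p + r <= 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def pu_criterion(recall_hat: float, positive_rate_hat: float) -> float:
    """Model-selection criterion r^2 / P[f(x)=1] (proportional to p*r)."""
    if positive_rate_hat <= 0.0:
        raise PUMetricsError("PU criterion undefined at positive rate 0")
    return recall_hat**2 / positive_rate_hat


def evaluate_pu(
    pred_on_heldout_positives: np.ndarray,
    pred_on_unlabeled: np.ndarray,
    class_prior: float | None = None,
) -> PUMetrics:
    """Full PU evaluation from predictions on the two validation pools.

    The validation set is the union of held-out known positives and the
    unlabeled pool.  ``class_prior`` defaults to the fraction of known
    positives in that union (the usual benchmark convention).
    """
    pred_pos = np.asarray(pred_on_heldout_positives)
    pred_unl = np.asarray(pred_on_unlabeled)
    r = estimate_recall(pred_pos)
    pred_all = np.concatenate([pred_pos, pred_unl]) if pred_unl.size else pred_pos
    rate = estimate_positive_rate(pred_all)
    if class_prior is None:
        class_prior = pred_pos.size / pred_all.size
    p = estimate_precision(r, class_prior, rate) if rate > 0 else 0.0
    return PUMetrics(
        recall_hat=r,
        positive_rate_hat=rate,
        class_prior=class_prior,
        precision_hat=p,
        f_measure=f_measure(p, r),
        pu_criterion=pu_criterion(r, rate) if rate > 0 else 0.0,
    )


def evaluate_naive(
    pred_on_heldout_positives: np.ndarray,
    pred_on_unlabeled: np.ndarray,
) -> PUMetrics:
    """Naive evaluation: unlabeled validation items counted as negatives.

    Precision then is tp/(tp+fp) with every unlabeled inlier counted as a
    false positive — the binary-classifier convention.
    """
    pred_pos = np.asarray(pred_on_heldout_positives)
    pred_unl = np.asarray(pred_on_unlabeled)
    r = estimate_recall(pred_pos)
    tp = int(np.sum(pred_pos == INLIER))
    fp = int(np.sum(pred_unl == INLIER))
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    pred_all = np.concatenate([pred_pos, pred_unl]) if pred_unl.size else pred_pos
    rate = estimate_positive_rate(pred_all)
    return PUMetrics(
        recall_hat=r,
        positive_rate_hat=rate,
        class_prior=pred_pos.size / pred_all.size,
        precision_hat=p,
        f_measure=f_measure(p, r),
        pu_criterion=pu_criterion(r, rate) if rate > 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------


def format_report(metrics: PUMetrics, title: str = "PU evaluation") -> str:
    """Flat key/value text table; percentages printed to 2 decimals."""
    pct = metrics.as_percent()
    lines = [f"# {title}"]
    lines.append(f"precision_pct\t{pct['precision']:.2f}")
    lines.append(f"recall_pct\t{pct['recall']:.2f}")
    lines.append(f"f_measure_pct\t{pct['f_measure']:.2f}")
    lines.append(f"positive_rate\t{metrics.positive_rate_hat:.6f}")
    lines.append(f"class_prior\t{metrics.class_prior:.6f}")
    lines.append(f"pu_criterion\t{metrics.pu_criterion:.6f}")
    return "\n".join(lines) + "\n"


def write_report(metrics: PUMetrics, txt_path, json_path, title: str = "PU evaluation") -> None:
    with open(txt_path, "w") as fh:
        fh.write(format_report(metrics, title))
    payload = asdict(metrics)
    payload.update({f"{k}_pct": v for k, v in metrics.as_percent().items()})
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)
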