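"""Evaluation metrics for the three-class peptide classifier.

Multi-class mode: accuracy, Cohen's kappa (KapS), and AU1U -- the Hand-Till
generalisation of the AUC, i.e. the mean over all unordered class pairs of
the two within-pair one-vs-one AUCs. Binary mode (ACP vs rest, obtained by
summing the AMP and negative probabilities): MCC, precision, sensitivity,
specificity, accuracy and AUC.

AUCs are rank-based (Mann-Whitney): the probability that a random positive
scores above a random negative, ties counting 1/2 -- identical to the
trapezoidal ROC area and reproducible on the discrete score sets produced
by forests.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .seqio import CLASSES


def _as_cm(cm) -> np.ndarray:
    arr = np.asarray(cm.values if isinstance(cm, pd.DataFrame) else cm, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError("confusion matrix must be square")
    if arr.sum() <= 0:
        raise ValidationError("confusion matrix is empty")
    if (arr < 0).any():
        raise ValidationError("confusion matrix entries must be non-negative")
    return arr


def confusion_matrix(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Sequence[str] = CLASSES,
) -> pd.DataFrame:
    """Counts of true class (rows) x predicted class (columns), fixed order."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValidationError("label vectors must be aligned and equal length")
    known = set(classes)
    for vec, name in ((y_true, "true"), (y_pred, "predicted")):
        bad = set(vec.tolist()) - known
        if bad:
            raise ValidationError(f"unknown {name} label(s): {sorted(bad)}")
    idx = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        out[idx[t], idx[p]] += 1
    return pd.DataFrame(out, index=list(classes), columns=list(classes))


def accuracy(cm) -> float:
    """Fraction of correctly classified samples: trace / total."""
    arr = _as_cm(cm)
    return float(np.trace(arr) / arr.sum())


def cohen_kappa(cm) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    If expected agreement p_e is exactly 1 (both marginals degenerate), the
    statistic is defined as 1 when observed agreement is also perfect and 0
    otherwise.
    """
    arr = _as_cm(cm)
    total = arr.sum()
    p_o = np.trace(arr) / total
    p_e = float((arr.sum(axis=1) * arr.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def binary_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC: P(score of random positive > score of random negative),
    ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D vectors")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("binary AUC requires both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def au1u(
    y_true: Sequence[str],
    probabilities: np.ndarray,
    classes: Sequence[str] = CLASSES,
) -> float:
    """Hand-Till AU1U: mean over unordered class pairs {i, j} of the average
    of A(i|j) (AUC of the class-i probability for i-vs-j, restricted to
    samples of those classes) and A(j|i).

    Pairs with a missing class are excluded with a warning; fewer than two
    classes present is an error.
    """
    y = np.asarray(y_true, dtype=object)
    P = np.asarray(probabilities, dtype=float)
    if P.ndim != 2 or P.shape[0] != y.shape[0] or P.shape[1] != len(classes):
        raise ValidationError("probability matrix must be n_samples x n_classes")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("probability rows must lie on the simplex")
    present = [c for c in classes if (y == c).any()]
    if len(present) < 2:
        raise ValidationError("AU1U requires at least two classes present")
    idx = {c: k for k, c in enumerate(classes)}
    pair_values = []
    for ci, cj in combinations(classes, 2):
        mask = (y == ci) | (y == cj)
        if not ((y == ci).any() and (y == cj).any()):
            warnings.warn(f"AU1U: pair ({ci}, {cj}) skipped; a class is absent")
            continue
        yi = (y[mask] == ci).astype(int)
        a_ij = binary_auc(P[mask, idx[ci]], yi)
        a_ji = binary_auc(P[mask, idx[cj]], 1 - yi)
        pair_values.append(0.5 * (a_ij + a_ji))
    return float(np.mean(pair_values))


def binarize_predictions(
    probabilities: np.ndarray,
    classes: Sequence[str] = CLASSES,
    positive: str = "ACP",
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Collapse three-class probabilities to a positive-vs-rest comparison.

    The rest score sums the remaining class probabilities (e.g. AMP + NEG);
    the decision is positive iff its probability strictly exceeds
    *threshold* (default 0.5).
    """
    P = np.asarray(probabilities, dtype=float)
    if P.ndim != 2 or P.shape[1] != len(classes):
        raise ValidationError("probability matrix must be n_samples x n_classes")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("probability rows must lie on the simplex")
    k = list(classes).index(positive)
    pos_score = P[:, k]
    rest_score = P.sum(axis=1) - pos_score
    decision = np.where(pos_score > threshold, positive, "rest")
    return pd.DataFrame(
        {
            f"prob_{positive}": pos_score,
            "prob_rest": rest_score,
            "decision": decision,
        }
    )


def binary_metrics(tp: int, fn: int, fp: int, tn: int) -> dict:
    """Binary confusion-cell metrics.

    MCC with any zero denominator factor is reported as 0; precision with no
    predicted positives is reported as missing (None).
    """
    total = tp + fn + fp + tn
    if total <= 0:
        raise ValidationError("empty binary confusion matrix")
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    prec = tp / (tp + fp) if (tp + fp) else None
    acc = (tp + tn) / total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    return {
        "mcc": float(mcc),
        "precision": None if prec is None else float(prec),
        "sensitivity": None if sens is None else float(sens),
        "specificity": None if spec is None else float(spec),
        "accuracy": float(acc),
    }


def multiclass_report(
    y_true: Sequence[str],
    probabilities: np.ndarray,
    decisions: Sequence[str],
    classes: Sequence[str] = CLASSES,
) -> dict:
    """Accuracy, AU1U and KapS in one pass (the three-class report columns)."""
    cm = confusion_matrix(y_true, decisions, classes)
    return {
        "accuracy": accuracy(cm),
        "au1u": au1u(y_true, probabilities, classes),
        "kaps": cohen_kappa(cm),
    }
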