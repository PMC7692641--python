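"""Exact permutation-test selection of informative n-grams (QuiPT).

For a binary feature (n-gram present/absent per 5-mer) and a binary target
(one class pair), the permutation distribution of any association statistic
depends only on the 2x2 contingency table. Conditioning on the margins, the
co-occurrence count ``n11`` follows a hypergeometric law under the null, so
the exact permutation p-value is a sum of hypergeometric masses over all
achievable tables whose statistic reaches the observed one -- no sampling
required.

The criterion statistic is information gain (mutual information between
feature and target) in natural-log units; it is exposed as a pluggable
function. A feature is *informative* when its p-value falls below the
threshold (default 1e-4) in at least one of the three pairwise class
contrasts (ACP/AMP, ACP/NEG, AMP/NEG); the selected pool is the union.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import hypergeom

from .errors import ValidationError
from .ngrams import FeatureMatrix, NGramDescriptor, descriptor_sort_key
from .seqio import CLASSES

#: Default significance threshold per contrast.
DEFAULT_ALPHA = 1e-4

#: The three ordered class-pair contrasts.
CONTRASTS = (("ACP", "AMP"), ("ACP", "NEG"), ("AMP", "NEG"))

#: Relative tolerance for statistic ties when accumulating the tail; needed
#: so the two extremes of a symmetric table both count as "at least as
#: extreme" despite floating-point noise.
TIE_RTOL = 1e-12


def _binary_entropy(p: np.ndarray | float) -> np.ndarray | float:
    p = np.asarray(p, dtype=float)
    return -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p))


def _ig_vector(n11: np.ndarray, n1_: float, n_1: float, N: float) -> np.ndarray:
    """Information gain H(target) - H(target | feature) for a vector of
    co-occurrence counts at fixed margins. Natural log; 0*log 0 = 0."""
    n11 = np.asarray(n11, dtype=float)
    h_target = _binary_entropy(n_1 / N)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_on = np.where(n1_ > 0, n11 / max(n1_, 1), 0.0)
        p_off = np.where(N - n1_ > 0, (n_1 - n11) / max(N - n1_, 1), 0.0)
    cond = (n1_ / N) * _binary_entropy(p_on) + ((N - n1_) / N) * _binary_entropy(p_off)
    return np.maximum(h_target - cond, 0.0)


def information_gain(n11: int, n1_: int, n_1: int, N: int) -> float:
    """Information gain of a 2x2 table given by its co-occurrence count and
    margins: ``n11`` = both feature and target positive, ``n1_`` = feature
    positives, ``n_1`` = target positives, ``N`` = total."""
    if N <= 0:
        raise ValidationError("N must be positive")
    if not (0 <= n1_ <= N and 0 <= n_1 <= N):
        raise ValidationError("margins must lie in [0, N]")
    lo, hi = max(0, n1_ + n_1 - N), min(n1_, n_1)
    if not (lo <= n11 <= hi):
        raise ValidationError(
            f"inconsistent contingency counts: n11={n11} outside [{lo}, {hi}]"
        )
    return float(_ig_vector(np.array([n11]), n1_, n_1, N)[0])


@dataclass(frozen=True)
class ContrastResult:
    """Outcome of one feature x contrast permutation test."""

    descriptor: NGramDescriptor | None
    contrast: tuple[str, str]
    statistic: float
    p_value: float


def exact_pvalue_from_counts(
    n11: int,
    n1_: int,
    n_1: int,
    N: int,
    criterion: Callable[[np.ndarray, float, float, float], np.ndarray] | None = None,
) -> tuple[float, float]:
    """Exact permutation (statistic, p-value) for given table counts.

    Sums hypergeometric mass over every achievable co-occurrence count whose
    statistic is >= the observed one (up to :data:`TIE_RTOL`). A constant
    feature or target gives statistic 0 and p = 1.
    """
    crit = criterion or _ig_vector
    stat_obs = float(crit(np.array([n11]), n1_, n_1, N)[0])
    lo, hi = max(0, n1_ + n_1 - N), min(n1_, n_1)
    support = np.arange(lo, hi + 1)
    stats = np.asarray(crit(support, n1_, n_1, N), dtype=float)
    pmf = hypergeom.pmf(support, N, n_1, n1_)
    if stat_obs <= 0.0:
        return 0.0, 1.0
    in_tail = stats >= stat_obs * (1.0 - TIE_RTOL)
    p = float(pmf[in_tail].sum())
    return stat_obs, min(max(p, 0.0), 1.0)


def quipt_pvalue(
    feature: Sequence[int] | np.ndarray,
    target: Sequence[int] | np.ndarray,
    contrast: tuple[str, str] = ("ACP", "AMP"),
    descriptor: NGramDescriptor | None = None,
    criterion: Callable | None = None,
) -> ContrastResult:
    """Exact permutation test of association between two binary vectors."""
    f = np.asarray(feature, dtype=int)
    t = np.asarray(target, dtype=int)
    if f.shape != t.shape or f.ndim != 1:
        raise ValidationError("feature and target must be equal-length 1-D vectors")
    if f.size < 2:
        raise ValidationError("need at least 2 observations")
    if not (set(np.unique(f)) <= {0, 1} and set(np.unique(t)) <= {0, 1}):
        raise ValidationError("feature and target must be binary (0/1)")
    N = int(f.size)
    n1_ = int(f.sum())
    n_1 = int(t.sum())
    n11 = int((f & t).sum())
    stat, p = exact_pvalue_from_counts(n11, n1_, n_1, N, criterion=criterion)
    return ContrastResult(descriptor, contrast, stat, p)


def select_informative(
    matrix: FeatureMatrix,
    labels: Sequence[str] | np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    criterion: Callable | None = None,
    combine: str = "union",
) -> tuple[list[NGramDescriptor], pd.DataFrame]:
    """Select n-grams informative in at least one pairwise class contrast.

    For each descriptor and each contrast, rows are restricted to the two
    classes and the exact permutation p-value computed. ``combine="union"``
    (default) keeps a descriptor if p < *alpha* in any contrast;
    ``"intersection"`` requires all three. Returns the selected descriptors
    in canonical order plus the full per-contrast audit report.
    """
    if labels is None:
        labels = matrix.labels()
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != matrix.shape[0]:
        raise ValidationError("labels must align with matrix rows")
    present = set(labels.tolist())
    for cls in CLASSES:
        if cls not in present:
            raise ValidationError(f"class {cls!r} absent from labels")
    if combine not in ("union", "intersection"):
        raise ValidationError("combine must be 'union' or 'intersection'")

    X = matrix.values.tocsc()
    n_desc = matrix.shape[1]
    records: list[dict] = []
    sig = np.zeros((n_desc, len(CONTRASTS)), dtype=bool)
    cache: dict[tuple[int, int, int, int], tuple[float, float]] = {}
    for ci, (a, b) in enumerate(CONTRASTS):
        mask = (labels == a) | (labels == b)
        y = (labels[mask] == a).astype(np.int64)
        Xc = X[np.flatnonzero(mask), :]
        N = int(mask.sum())
        n_1 = int(y.sum())
        n11s = np.asarray(y @ Xc).ravel().astype(int)
        n1_s = np.asarray(Xc.sum(axis=0)).ravel().astype(int)
        for j in range(n_desc):
            key = (int(n11s[j]), int(n1_s[j]), n_1, N)
            if key not in cache:
                cache[key] = exact_pvalue_from_counts(*key, criterion=criterion)
            stat, p = cache[key]
            sig[j, ci] = p < alpha
            records.append(
                {
                    "descriptor": matrix.descriptors[j].text,
                    "contrast": f"{a}/{b}",
                    "statistic": stat,
                    "p_value": p,
                }
            )
    if combine == "union":
        keep = sig.any(axis=1)
    else:
        keep = sig.all(axis=1)
    selected = sorted(
        (d for d, k in zip(matrix.descriptors, keep) if k), key=descriptor_sort_key
    )
    report = pd.DataFrame.from_records(records)
    selected_texts = {d.text for d in selected}
    report["selected"] = report["descriptor"].isin(selected_texts)
    return selected, report
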