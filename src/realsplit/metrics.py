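"""Dual regression-classification scoring for virtual screening.

Models are trained as regressors of pGI50, but evaluated the way a
prospective screen uses them: measured activities are binarized at a potency
threshold (active iff pGI50 > 6, i.e. GI50 below 1 uM), and predictions are
binarized by rank — the top k=100 predicted molecules are the "purchases".
Hit rate (the fraction of purchases that are measured actives) is the primary
metric; MCC, RMSE and ROC AUC complete the report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Measured-activity threshold: active iff pGI50 strictly greater than this.
ACTIVITY_THRESHOLD = 6.0
#: Number of top-ranked predictions declared positive (the screening budget).
K_TOP = 100


@dataclass
class PredictionTable:
    """Merged out-of-fold predictions for one (dataset, split, learner, seed).

    ``df`` columns: id, y (measured pGI50), y_hat (predicted pGI50), fold.
    Each molecule appears exactly once.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"id", "y", "y_hat"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"PredictionTable missing columns {missing}")
        if self.df["id"].duplicated().any():
            dupes = self.df.loc[self.df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate molecule IDs in predictions: {dupes[:5]}")
        if not np.isfinite(self.df[["y", "y_hat"]].to_numpy()).all():
            raise ValueError("non-finite y or y_hat in PredictionTable")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    """One merged evaluation: hit rate (%), MCC, RMSE, ROC AUC plus provenance.

    ``hit_rate_pct`` and ``roc_auc`` are NaN when undefined (no predicted
    positives / single-class labels).
    """

    hit_rate_pct: float
    mcc: float
    rmse: float
    roc_auc: float
    counts: ConfusionCounts
    k_top: int = K_TOP
    activity_threshold: float = ACTIVITY_THRESHOLD
    metadata: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flatten into one row of a tidy results table."""
        row = dict(self.metadata)
        row.update(hit_rate=self.hit_rate_pct, mcc=self.mcc, rmse=self.rmse,
                   roc_auc=self.roc_auc, tp=self.counts.tp, fp=self.counts.fp,
                   tn=self.counts.tn, fn=self.counts.fn, k=self.k_top,
                   threshold=self.activity_threshold)
        return row


def binarize_measured(y, threshold: float = ACTIVITY_THRESHOLD) -> np.ndarray:
    """Active (1) iff measured pGI50 strictly exceeds the threshold.

    Exactly-threshold values are negatives (a molecule at pGI50 = 6.0 is
    inactive under the 1 uM potency cutoff).
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite measured values")
    return (y > threshold).astype(np.int8)


def topk_predicted_positives(y_hat, k: int = K_TOP) -> np.ndarray:
    """Declare the k highest-scoring molecules predicted positives.

    Ties at the k-th rank are broken by input order (stable sort), so the
    result is deterministic.  When the test set holds fewer than k molecules
    everything is positive and a warning is emitted; small per-dataset test
    sets still evaluate rather than erroring.
    """
    y_hat = np.asarray(y_hat, dtype=float)
    if y_hat.size == 0:
        raise ValueError("empty prediction vector")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = y_hat.size
    if n < k:
        warnings.warn(f"test set has n={n} < k={k}; all molecules predicted positive")
        k = n
    order = np.argsort(-y_hat, kind="stable")
    predicted = np.zeros(n, dtype=np.int8)
    predicted[order[:k]] = 1
    return predicted


def confusion(labels, predicted) -> ConfusionCounts:
    """2x2 tally of binary labels vs binary predictions."""
    labels = np.asarray(labels, dtype=bool)
    predicted = np.asarray(predicted, dtype=bool)
    if labels.shape != predicted.shape:
        raise ValueError("labels and predictions differ in length")
    return ConfusionCounts(
        tp=int(np.sum(labels & predicted)),
        tn=int(np.sum(~labels & ~predicted)),
        fp=int(np.sum(~labels & predicted)),
        fn=int(np.sum(labels & ~predicted)),
    )


def hit_rate(c: ConfusionCounts) -> float:
    """Percentage of predicted positives that are measured actives.

    100 * TP / (TP + FP); NaN when nothing was predicted positive (cannot
    happen under top-k binarization, but can for user-supplied labels).
    """
    if c.tp + c.fp == 0:
        return math.nan
    return 100.0 * c.tp / (c.tp + c.fp)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def roc_auc(labels, scores) -> float:
    """Rank-based ROC AUC with midrank tie handling.

    Equals P(score_pos > score_neg) + 0.5 * P(tie), the Mann-Whitney form.
    Returns NaN with a warning when labels are single-class.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores differ in length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("single-class labels: ROC AUC undefined")
        return math.nan
    ranks = stats.rankdata(scores)  # midranks for ties
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def rmse(y, y_hat) -> float:
    """Root mean squared error between measured and predicted pGI50."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def metric_correlations(pairs) -> tuple[float, float]:
    """(Pearson r, Spearman rho) between two metrics over evaluation records.

    ``pairs`` is a sequence of (metric_a, metric_b); records with NaN in
    either coordinate are dropped (count reported via warning).  At least
    three valid pairs are required.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (a, b) tuples")
    valid = np.isfinite(arr).all(axis=1)
    dropped = int((~valid).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} pairs with undefined values")
    arr = arr[valid]
    if arr.shape[0] < 3:
        raise ValueError(f"need >= 3 valid pairs, got {arr.shape[0]}")
    pearson = stats.pearsonr(arr[:, 0], arr[:, 1]).statistic
    spearman = stats.spearmanr(arr[:, 0], arr[:, 1]).statistic
    return float(pearson), float(spearman)
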