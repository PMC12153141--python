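"""Train/test distribution-shift and clustering-quality diagnostics.

The central shift statistic: for every test molecule, the maximum Tanimoto
similarity to any training molecule (its structural nearest neighbor),
computed on 2048-bit radius-2 Morgan fingerprints.  Lower values mean a
larger distributional shift and hence a harder, more prospective-like split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)

#: pGI50 histogram bin edges; the last bin is open-ended (> 7).
ACTIVITY_BINS = (4.0, 5.0, 6.0, 7.0)


@dataclass
class ShiftReport:
    """Per-test-molecule max train similarity plus summary statistics."""

    max_similarity: np.ndarray          # one value in [0,1] per test molecule
    fingerprint_bits: int = 2048
    fingerprint_radius: int = 2
    metadata: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(self.max_similarity.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.max_similarity))

    def quartiles(self) -> tuple[float, float, float]:
        q1, q2, q3 = np.percentile(self.max_similarity, [25, 50, 75])
        return float(q1), float(q2), float(q3)

    def summary(self) -> dict:
        q1, q2, q3 = self.quartiles()
        return {"n_test": int(self.max_similarity.size), "mean": self.mean,
                "q1": q1, "median": q2, "q3": q3,
                "fingerprint_bits": self.fingerprint_bits,
                "fingerprint_radius": self.fingerprint_radius,
                **self.metadata}


@dataclass
class ClusterQualityReport:
    silhouette: float           # [-1, 1]; NaN when undefined
    davies_bouldin: float       # >= 0, lower is better; NaN when undefined
    calinski_harabasz: float    # >= 0, higher is better; NaN when undefined
    n_singletons: int
    distance: str = "euclidean"


def _tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All-pairs Tanimoto between the rows of two 0/1 matrices."""
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    inter = A.astype(np.float32) @ B.astype(np.float32).T
    union = A.sum(1, dtype=np.float32)[:, None] + B.sum(1, dtype=np.float32)[None, :] - inter
    # all-zero vs all-zero pairs: union 0 -> similarity 1 by convention
    return np.where(union > 0, inter / np.maximum(union, 1e-30), 1.0)


def max_train_similarity(test_fps, train_fps, metadata: dict | None = None,
                         ) -> ShiftReport:
    """Max Tanimoto similarity of each test molecule to the training set.

    Fingerprints must share one length (2048 bits, radius 2 by convention for
    diagnostics).  Monotone in the training set: adding training molecules
    can only raise the per-molecule maxima.
    """
    test = np.asarray(np.stack(list(test_fps)), dtype=bool)
    if len(train_fps) == 0:
        raise ValueError("empty training set")
    train = np.asarray(np.stack(list(train_fps)), dtype=bool)
    if test.shape[1] != train.shape[1]:
        raise ValueError("test/train fingerprint length mismatch")
    best = _tanimoto_matrix(test, train).max(axis=1)
    return ShiftReport(best, fingerprint_bits=test.shape[1],
                       metadata=dict(metadata or {}))


def split_shift_report(fps_by_id: dict[str, np.ndarray], assignment,
                       pool: str = "molecules") -> ShiftReport:
    """Shift report across all k folds of a split (each fold tested once).

    ``pool="molecules"`` concatenates per-molecule maxima over folds;
    ``pool="folds"`` averages within each fold first, yielding k values.
    """
    values = []
    for fold in range(assignment.k):
        test_ids = assignment.test_ids(fold)
        train_ids = assignment.train_ids(fold)
        if not test_ids or not train_ids:
            continue
        rep = max_train_similarity([fps_by_id[i] for i in test_ids],
                                   [fps_by_id[i] for i in train_ids])
        if pool == "folds":
            values.append([rep.mean])
        else:
            values.append(rep.max_similarity)
    flat = np.concatenate([np.asarray(v, dtype=float) for v in values])
    return ShiftReport(flat, metadata={"strategy": assignment.strategy,
                                       "pool": pool})


def cluster_quality(points, labels, distance: str = "euclidean",
                    ) -> ClusterQualityReport:
    """Silhouette, Davies-Bouldin and Calinski-Harabasz for one clustering.

    ``distance="jaccard"`` evaluates the silhouette on Jaccard distances
    (1 - Tanimoto), the natural choice for binary fingerprints; the
    Davies-Bouldin and Calinski-Harabasz indices are centroid-based and are
    always computed in Euclidean space on the points as given.  A
    single-cluster or all-singleton labeling yields NaN indices with a
    warning rather than an error.
    """
    X = np.asarray(points, dtype=bool if distance == "jaccard" else float)
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    n_singletons = int((counts == 1).sum())
    if len(counts) < 2 or len(counts) >= len(labels):
        warnings.warn("degenerate clustering: quality indices undefined")
        return ClusterQualityReport(float("nan"), float("nan"), float("nan"),
                                    n_singletons, distance)
    sil = silhouette_score(X, labels, metric=distance)
    return ClusterQualityReport(
        silhouette=float(sil),
        davies_bouldin=float(davies_bouldin_score(X, labels)),
        calinski_harabasz=float(calinski_harabasz_score(X, labels)),
        n_singletons=n_singletons,
        distance=distance,
    )


def activity_histogram(y) -> dict[str, int]:
    """Counts of pGI50 values in the bins [4,5), [5,6), [6,7), [7, inf).

    Values below 4 (possible only in data without the floor-censoring the
    bins assume) land in an ``underflow`` bucket and trigger a warning.
    Counts, including underflow, sum to n.
    """
    y = np.asarray(y, dtype=float)
    if y.size and not np.isfinite(y).all():
        raise ValueError("non-finite activity values")
    lo, mid1, mid2, hi = ACTIVITY_BINS
    counts = {
        "underflow": int((y < lo).sum()),
        "4-5": int(((y >= lo) & (y < mid1)).sum()),
        "5-6": int(((y >= mid1) & (y < mid2)).sum()),
        "6-7": int(((y >= mid2) & (y < hi)).sum()),
        ">7": int((y >= hi).sum()),
    }
    if counts["underflow"]:
        warnings.warn(f"{counts['underflow']} values below the pGI50 floor of 4")
    return counts


def write_shift_report(report: ShiftReport, path, ids=None) -> None:
    """Write the per-molecule similarity table (TSV) plus a JSON summary sidecar."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    df = pd.DataFrame({"max_train_similarity": report.max_similarity})
    if ids is not None:
        df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(report.summary(), indent=2))


def completeness_percent(n_determinations: int, n_molecules: int,
                         n_datasets: int) -> float:
    """Label-matrix completeness: determinations / (molecules x datasets) as %."""
    denom = n_molecules * n_datasets
    if denom <= 0:
        raise ValueError("molecule and dataset counts must be positive")
    return 100.0 * n_determinations / denom
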