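"""Merged sevenfold cross-validation over (learner x dataset x split x seed).

For each dataset and split, every fold is held out once, out-of-fold
predictions from all k folds are concatenated, and the metric suite is
computed once on the merged table — not averaged over per-fold metrics.
Merging evaluates every labeled molecule exactly once and keeps the top-k
binarization meaningful on small, uneven test folds.

Baseline learners are ordinary least squares and a 100-tree bagged random
forest (scikit-learn defaults: squared-error criterion, unlimited depth,
max_features=1.0, bootstrap).  External models plug in through a subprocess
adapter that reads train/test tables and emits a prediction table.
"""

from __future__ import annotations

import hashlib
import itertools
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression

from .chem import MoleculeRecord, featurize
from .metrics import (ACTIVITY_THRESHOLD, K_TOP, MetricReport, PredictionTable,
                      binarize_measured, confusion, hit_rate, mcc, rmse,
                      roc_auc, topk_predicted_positives)
from .splits import FoldAssignment, restrict_to_dataset

LEARNERS = ("linear", "forest", "external-adapter")


@dataclass
class RunDescriptor:
    learner: str
    dataset: str
    split: str
    fold: int
    seed: int

    def key(self) -> str:
        tag = f"{self.learner}|{self.dataset}|{self.split}|{self.fold}|{self.seed}"
        return hashlib.sha1(tag.encode()).hexdigest()[:16]


@dataclass
class BenchmarkManifest:
    """Cross-product enumeration of every fold-level training run.

    One entry per (learner, dataset, fold, seed); the split strategies are an
    evaluation axis recorded on the manifest but not multiplied into the
    entry count, so a 4-learner x 60-dataset x 7-fold x 5-seed benchmark
    counts 8400 trained models.
    """

    learners: list[str]
    datasets: list[str]
    splits: list[str]
    k_folds: int
    seeds: list[int]
    entries: list[RunDescriptor] = field(default_factory=list)

    def n_evaluations_per_cell(self) -> int:
        """Merged evaluation records per (learner, split): |seeds| x |datasets|."""
        return len(self.seeds) * len(self.datasets)


def build_manifest(learners, datasets, splits, k_folds: int = 7,
                   seeds=(0, 1, 2, 3, 4)) -> BenchmarkManifest:
    """Enumerate every (learner, dataset, fold, seed) run, in a fixed order."""
    learners, datasets, splits, seeds = (list(learners), list(datasets),
                                         list(splits), list(seeds))
    for name, axis in [("learners", learners), ("datasets", datasets),
                       ("splits", splits), ("seeds", seeds)]:
        if not axis:
            raise ValueError(f"empty manifest axis: {name}")
    if k_folds < 1:
        raise ValueError("k_folds must be >= 1")
    entries = [
        RunDescriptor(le, d, "*", f, se)
        for le, d, se, f in itertools.product(
            learners, datasets, seeds, range(k_folds))
    ]
    return BenchmarkManifest(learners, datasets, splits, k_folds, list(seeds), entries)


def make_learner(name: str, seed: int = 0):
    """Instantiate a baseline learner with the benchmark's hyperparameters."""
    if name == "linear":
        return LinearRegression(fit_intercept=True)
    if name == "forest":
        return RandomForestRegressor(
            n_estimators=100, criterion="squared_error", max_depth=None,
            min_samples_split=2, min_samples_leaf=1, max_features=1.0,
            bootstrap=True, random_state=seed, n_jobs=1)
    raise ValueError(f"unknown learner {name!r}; expected one of {LEARNERS}")


def run_fold(X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray,
             learner: str = "forest", seed: int = 0,
             external_cmd: str | None = None) -> np.ndarray:
    """Fit one learner on the training fold and predict the held-out fold.

    ``external-adapter`` shells out to ``external_cmd`` with three file
    arguments: a train table (feature columns + y), a test table (features
    only) and an output path where the command must write one prediction per
    line.  Baseline learners are fit in-process.
    """
    y_train = np.asarray(y_train, dtype=float)
    if len(X_train) < 2:
        raise ValueError(f"degenerate train set: {len(X_train)} rows")
    if np.ptp(y_train) == 0:
        raise ValueError("degenerate train set: constant target")
    if learner == "external-adapter":
        if not external_cmd:
            raise ValueError("external-adapter requires external_cmd")
        return _run_external(X_train, y_train, X_test, external_cmd)
    model = make_learner(learner, seed=seed)
    model.fit(np.asarray(X_train, dtype=float), y_train)
    return model.predict(np.asarray(X_test, dtype=float))


def _run_external(X_train, y_train, X_test, cmd: str) -> np.ndarray:
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        train = pd.DataFrame(np.asarray(X_train, dtype=float))
        train["y"] = y_train
        train.to_csv(tmp / "train.tsv", sep="\t", index=False)
        pd.DataFrame(np.asarray(X_test, dtype=float)).to_csv(
            tmp / "test.tsv", sep="\t", index=False)
        out = tmp / "pred.txt"
        subprocess.run(
            [*cmd.split(), str(tmp / "train.tsv"), str(tmp / "test.tsv"), str(out)],
            check=True)
        preds = np.loadtxt(out, ndmin=1)
    if preds.shape[0] != len(X_test):
        raise ValueError("external adapter returned wrong number of predictions")
    return preds


def merge_fold_predictions(per_fold: list[pd.DataFrame],
                           metadata: dict | None = None) -> PredictionTable:
    """Concatenate out-of-fold prediction frames into one merged table.

    Each frame needs columns id, y, y_hat, fold; fold ID sets must be
    pairwise disjoint so every molecule gets exactly one out-of-fold
    prediction.
    """
    frames = [f for f in per_fold if len(f)]
    if not frames:
        raise ValueError("no fold predictions to merge")
    merged = pd.concat(frames, ignore_index=True)
    if merged["id"].duplicated().any():
        raise ValueError("fold_overlap: molecule predicted in more than one fold")
    meta = dict(metadata or {})
    meta["contributing_folds"] = sorted(merged["fold"].unique().tolist())
    return PredictionTable(merged, meta)


def evaluate_merged(table: PredictionTable, k: int = K_TOP,
                    threshold: float = ACTIVITY_THRESHOLD) -> MetricReport:
    """Score one merged prediction table with the full dual metric suite."""
    y = table.df["y"].to_numpy(dtype=float)
    y_hat = table.df["y_hat"].to_numpy(dtype=float)
    labels = binarize_measured(y, threshold=threshold)
    predicted = topk_predicted_positives(y_hat, k=k)
    counts = confusion(labels, predicted)
    return MetricReport(
        hit_rate_pct=hit_rate(counts),
        mcc=mcc(counts),
        rmse=rmse(y, y_hat),
        roc_auc=roc_auc(labels, y_hat),
        counts=counts,
        k_top=min(k, len(y)),
        activity_threshold=threshold,
        metadata=dict(table.metadata),
    )


def cross_validate(records: list[MoleculeRecord], dataset: str,
                   assignment: FoldAssignment, learner: str = "forest",
                   seed: int = 0, k_top: int = K_TOP,
                   threshold: float = ACTIVITY_THRESHOLD,
                   features: dict[str, np.ndarray] | None = None,
                   external_cmd: str | None = None) -> MetricReport:
    """Merged k-fold cross-validation of one learner on one labeled dataset.

    ``assignment`` is the master split; it is restricted to the molecules
    labeled for ``dataset`` first.  Empty test folds (possible after
    restriction) are skipped.  ``features`` may carry precomputed 263-vectors
    keyed by molecule ID to avoid refeaturizing across datasets.
    """
    labeled = {r.id: r for r in records if dataset in r.labels}
    restricted = restrict_to_dataset(assignment, set(labeled))
    if features is None:
        features = {rid: featurize(labeled[rid]) for rid in labeled}
    per_fold = []
    for fold in range(restricted.k):
        test_ids = restricted.test_ids(fold)
        if not test_ids:
            continue
        train_ids = restricted.train_ids(fold)
        X_train = np.stack([features[i] for i in train_ids])
        y_train = np.array([labeled[i].labels[dataset] for i in train_ids])
        X_test = np.stack([features[i] for i in test_ids])
        preds = run_fold(X_train, y_train, X_test, learner=learner, seed=seed,
                         external_cmd=external_cmd)
        per_fold.append(pd.DataFrame(
            {"id": test_ids,
             "y": [labeled[i].labels[dataset] for i in test_ids],
             "y_hat": preds, "fold": fold}))
    table = merge_fold_predictions(
        per_fold, metadata={"dataset": dataset, "split": assignment.strategy,
                            "learner": learner, "seed": seed})
    return evaluate_merged(table, k=k_top, threshold=threshold)


def run_benchmark(records: list[MoleculeRecord], datasets: list[str],
                  split_assignments: dict[str, dict[int, FoldAssignment]],
                  learners=("linear", "forest"), k_top: int = K_TOP,
                  threshold: float = ACTIVITY_THRESHOLD,
                  cache_dir: str | Path | None = None) -> pd.DataFrame:
    """Run the full benchmark grid and return a tidy results table.

    ``split_assignments`` maps strategy -> {seed -> master FoldAssignment}
    (deterministic strategies may map every seed to the same assignment; the
    seed still varies learner randomness).  One row per merged evaluation,
    i.e. per (learner, dataset, split, seed).  With ``cache_dir`` set, each
    finished evaluation is written to disk and reloaded on rerun, so an
    interrupted benchmark resumes.
    """
    features = {r.id: featurize(r) for r in records}
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    rows = []
    for strategy, by_seed in split_assignments.items():
        for seed, assignment in by_seed.items():
            for learner in learners:
                for dataset in datasets:
                    desc = RunDescriptor(learner, dataset, strategy, -1, seed)
                    if cache:
                        hit = cache / f"{desc.key()}.json"
                        if hit.exists():
                            rows.append(pd.read_json(hit, typ="series").to_dict())
                            continue
                    report = cross_validate(
                        records, dataset, assignment, learner=learner,
                        seed=seed, k_top=k_top, threshold=threshold,
                        features=features)
                    row = report.to_row()
                    if cache:
                        pd.Series(row).to_json(cache / f"{desc.key()}.json")
                    rows.append(row)
    return pd.DataFrame(rows)


# -- statistical comparison layer -------------------------------------------

#: p-value annotation scale used on comparison reports.
ANNOTATION_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_annotation(p: float) -> str:
    """Map a p-value to the star annotation: ns, *, **, ***, ****."""
    if not (0 <= p <= 1):
        raise ValueError(f"p-value {p} outside [0, 1]")
    for cut, stars in ANNOTATION_THRESHOLDS:
        if p <= cut:
            return stars
    return "ns"


@dataclass
class ComparisonReport:
    """Pairwise model comparison for one split strategy and metric."""

    split: str
    metric: str
    medians: dict[str, float]
    p_values: dict[tuple[str, str], float]
    annotations: dict[tuple[str, str], str]
    n_pairs: int
    n_dropped: int = 0

    def to_json_dict(self) -> dict:
        return {
            "split": self.split, "metric": self.metric,
            "medians": self.medians,
            "comparisons": [
                {"a": a, "b": b, "p": self.p_values[(a, b)],
                 "annotation": self.annotations[(a, b)]}
                for a, b in self.p_values
            ],
            "n_pairs": self.n_pairs, "n_dropped": self.n_dropped,
        }


def compare_models(results: pd.DataFrame, metric: str, split: str,
                   holm: bool = False) -> ComparisonReport:
    """Paired two-sided Wilcoxon signed-rank tests between models.

    Records are paired on (dataset, seed); every model must have one record
    for each pair present, otherwise a pairing violation is raised.  Pairs
    with an undefined metric for any model are dropped listwise (count
    reported).  ``holm`` applies Holm step-down correction across the
    pairwise tests (off by default).
    """
    sub = results[results["split"] == split]
    if sub.empty:
        raise ValueError(f"no results for split {split!r}")
    wide = sub.pivot_table(index=["dataset", "seed"], columns="learner",
                           values=metric, aggfunc="first")
    models = sorted(wide.columns)
    if wide.isna().any(axis=None):
        # distinguish a missing record (pairing violation) from a NaN metric
        counts = sub.groupby(["dataset", "seed"])["learner"].nunique()
        if (counts != len(models)).any():
            raise ValueError("pairing_violation: models lack records for some "
                             "(dataset, seed) pairs")
    n_total = len(wide)
    wide = wide.dropna()
    n_dropped = n_total - len(wide)
    medians = {m: float(wide[m].median()) for m in models}
    p_values: dict[tuple[str, str], float] = {}
    pairs = list(itertools.combinations(models, 2))
    for a, b in pairs:
        diff = wide[a] - wide[b]
        if np.allclose(diff, 0):
            p = 1.0  # identical records carry no evidence of a difference
        else:
            p = float(stats.wilcoxon(wide[a], wide[b],
                                     alternative="two-sided").pvalue)
        p_values[(a, b)] = p
    if holm and pairs:
        order = sorted(pairs, key=lambda ab: p_values[ab])
        m = len(order)
        running = 0.0
        for i, ab in enumerate(order):
            running = max(running, min(1.0, (m - i) * p_values[ab]))
            p_values[ab] = running
    annotations = {ab: significance_annotation(p) for ab, p in p_values.items()}
    return ComparisonReport(split, metric, medians, p_values, annotations,
                            n_pairs=len(wide), n_dropped=n_dropped)
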