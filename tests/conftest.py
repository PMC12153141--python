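"""Shared fixtures: the synthetic library and the forest benchmark run.

The benchmark fixture is session-scoped and deliberately heavy (four split
strategies x 5 seeds x 10 datasets with the 100-tree forest learner); every
test that needs benchmark results shares the single run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import realsplit as rs
from realsplit.chem import fingerprint

BENCHMARK_SEEDS = (0, 1, 2, 3, 4)
STRATEGIES = ("random", "scaffold", "butina", "umap")


@pytest.fixture(scope="session")
def library():
    """Default synthetic library: 7 families x 50 molecules, 10 datasets."""
    records, truth = rs.make_benchmark_library()
    return records, truth


@pytest.fixture(scope="session")
def fps2048(library):
    """Similarity fingerprints (2048 bits, radius 2) keyed by molecule ID."""
    records, _ = library
    return {r.id: fingerprint(r, n_bits=2048) for r in records}


@pytest.fixture(scope="session")
def master_splits(library, fps2048):
    """Master fold assignments: strategy -> {seed -> FoldAssignment}.

    Scaffold and Butina splits are deterministic given input order, so every
    seed maps to the same assignment; the seed still varies the learner.
    """
    records, _ = library
    ids = [r.id for r in records]
    fps = [fps2048[i] for i in ids]
    scaffold = rs.scaffold_split(records, k=7)
    butina = rs.butina_split(rs.butina_cluster(fps, cutoff=0.4, ids=ids), k=7)
    out = {"random": {}, "scaffold": {}, "butina": {}, "umap": {}}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in BENCHMARK_SEEDS:
            out["random"][seed] = rs.random_split(ids, k=7, seed=seed)
            out["scaffold"][seed] = scaffold
            out["butina"][seed] = butina
            out["umap"][seed] = rs.umap_cluster_split(fps, n_clusters=7,
                                                      seed=seed, ids=ids)
    return out


@pytest.fixture(scope="session")
def benchmark_results(library, master_splits):
    """Forest-learner benchmark over all strategies, seeds and datasets.

    Returns a tidy DataFrame with one row per merged evaluation
    (dataset, split, seed): hit_rate, mcc, rmse, roc_auc and counts.
    """
    records, _ = library
    datasets = sorted({d for r in records for d in r.labels})
    df = rs.run_benchmark(records, datasets, master_splits,
                          learners=("forest",))
    assert len(df) == len(STRATEGIES) * len(BENCHMARK_SEEDS) * len(datasets)
    return df


@pytest.fixture(scope="session")
def shift_means(master_splits, fps2048):
    """Mean max-Tanimoto train/test similarity per (strategy, seed)."""
    rows = []
    for strategy, by_seed in master_splits.items():
        for seed, assignment in by_seed.items():
            rep = rs.split_shift_report(fps2048, assignment)
            rows.append({"split": strategy, "seed": seed, "mean_max_sim": rep.mean})
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
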