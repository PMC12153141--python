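"""Four train/test splitting strategies for molecular datasets.

A split is a k-fold partition of a molecule set (default k=7, each fold used
once as a test set).  The strategies differ in how much train/test structural
similarity they allow:

* ``random`` — seeded shuffle dealt into near-equal folds.
* ``scaffold`` — molecules sharing a Bemis-Murcko scaffold stay in one fold.
* ``butina`` — sphere-exclusion clusters on fingerprint distances packed
  whole into folds.
* ``umap`` — UMAP embedding of fingerprints + agglomerative clustering; the
  clusters *are* the folds (sizes intentionally uneven).

Splits are computed once on the master molecule set and then restricted to
each dataset's labeled subset with :func:`restrict_to_dataset`, so a molecule
keeps the same fold index in every dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from hashlib import blake2b

import numpy as np

from .chem import MoleculeRecord


class SplitError(ValueError):
    """Raised for invalid split requests (see message for the reason code)."""


@dataclass
class FoldAssignment:
    """A k-fold partition of molecule IDs with its provenance.

    ``fold_of`` maps molecule ID to a 0-based fold index in [0, k); reports
    and serialized files use 1-based fold numbers.
    """

    strategy: str            # random | scaffold | butina | umap
    k: int
    seed: int | None
    fold_of: dict[str, int]
    params: dict = field(default_factory=dict)

    def validate(self) -> "FoldAssignment":
        """Check the exactly-once partition property and index range."""
        for mol_id, fold in self.fold_of.items():
            if not (0 <= fold < self.k):
                raise SplitError(
                    f"fold index {fold} for {mol_id!r} outside [0, {self.k})")
        return self

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for fold in self.fold_of.values():
            sizes[fold] += 1
        return sizes

    def n_molecules(self) -> int:
        return len(self.fold_of)

    def test_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.fold_of.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.fold_of.items() if f != fold]


@dataclass
class ClusterSet:
    """Molecule-ID -> cluster-index labels from one clustering method."""

    labels: dict[str, int]
    method: str              # butina | umap_agglomerative
    params: dict = field(default_factory=dict)

    def clusters(self) -> list[list[str]]:
        """Member lists indexed by cluster, preserving insertion order."""
        n = max(self.labels.values()) + 1 if self.labels else 0
        out: list[list[str]] = [[] for _ in range(n)]
        for mol_id, c in self.labels.items():
            out[c].append(mol_id)
        return out

    def n_singletons(self) -> int:
        return sum(1 for c in self.clusters() if len(c) == 1)


def random_split(ids: list[str], k: int = 7, seed: int = 0) -> FoldAssignment:
    """Shuffle IDs with a seeded generator and deal into k near-equal folds.

    Fold sizes differ by at most one: the first ``n mod k`` folds get the
    extra molecule.
    """
    ids = list(ids)
    if not ids:
        raise SplitError("empty ID list")
    if k < 1 or k > len(ids):
        raise SplitError(f"k={k} invalid for {len(ids)} molecules")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    base, extra = divmod(len(ids), k)
    fold_of: dict[str, int] = {}
    pos = 0
    for fold in range(k):
        size = base + (1 if fold < extra else 0)
        for idx in order[pos:pos + size]:
            fold_of[ids[idx]] = fold
        pos += size
    return FoldAssignment("random", k, seed, fold_of).validate()


def _pack_groups(groups: list[tuple[str, list[str]]], k: int,
                 strategy: str, seed: int | None, params: dict) -> FoldAssignment:
    """Greedy-balanced packing: groups by descending size into smallest fold.

    Ties on group size broken by input order; ties on fold size by lowest
    fold index.  Deterministic.
    """
    if len(groups) < k:
        raise SplitError(
            f"insufficient_groups: {len(groups)} groups for k={k} folds")
    order = sorted(range(len(groups)), key=lambda i: (-len(groups[i][1]), i))
    sizes = [0] * k
    fold_of: dict[str, int] = {}
    for gi in order:
        fold = min(range(k), key=lambda f: (sizes[f], f))
        for mol_id in groups[gi][1]:
            fold_of[mol_id] = fold
        sizes[fold] += len(groups[gi][1])
    return FoldAssignment(strategy, k, seed, fold_of, params).validate()


def scaffold_split(records: list[MoleculeRecord], k: int = 7,
                   strategy_order: str = "greedy-balanced") -> FoldAssignment:
    """Group molecules by Bemis-Murcko scaffold and assign whole groups to folds.

    The acyclic (empty-scaffold) molecules form one group of their own.  Two
    orders are available: ``greedy-balanced`` (default; largest group first
    into the currently smallest fold, giving near-equal folds) and ``hash``
    (stable hash of the scaffold key mod k, giving uneven folds but assignment
    independent of the rest of the library).
    """
    from .chem import murcko_scaffold

    groups: dict[str, list[str]] = {}
    for r in records:
        key = r.scaffold if r.scaffold is not None else murcko_scaffold(r)
        groups.setdefault(key, []).append(r.id)
    params = {"order": strategy_order}
    if strategy_order == "greedy-balanced":
        return _pack_groups([(s, m) for s, m in groups.items()], k,
                            "scaffold", None, params)
    if strategy_order == "hash":
        if len(groups) < k:
            raise SplitError(
                f"insufficient_groups: {len(groups)} groups for k={k} folds")
        fold_of = {}
        for key, members in groups.items():
            h = int.from_bytes(blake2b(key.encode(), digest_size=8).digest(), "big")
            for mol_id in members:
                fold_of[mol_id] = h % k
        return FoldAssignment("scaffold", k, None, fold_of, params).validate()
    raise SplitError(f"unknown strategy_order {strategy_order!r}")


def butina_cluster(fps: list[np.ndarray], cutoff: float = 0.4,
                   ids: list[str] | None = None) -> ClusterSet:
    """Sphere-exclusion (Butina) clustering on Tanimoto distances.

    Two molecules are neighbors when their Tanimoto *distance* (1 - similarity)
    is at most ``cutoff``.  The unassigned molecule with the most unassigned
    neighbors becomes the next cluster centroid and absorbs its unassigned
    neighbors, so every member is within ``cutoff`` of its centroid.  Ties are
    broken by lowest input index; the result is deterministic given input
    order.  Dissimilar libraries typically yield many singleton clusters.
    """
    n = len(fps)
    if ids is None:
        ids = [str(i) for i in range(n)]
    if n == 0:
        return ClusterSet({}, "butina", {"cutoff": cutoff})
    X = np.asarray(np.stack(fps), dtype=bool)
    # pairwise Tanimoto via bit counts; float matmul is fastest at this scale
    Xf = X.astype(np.float32)
    inter = Xf @ Xf.T
    ones = X.sum(axis=1).astype(np.float32)
    union = ones[:, None] + ones[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-30), 1.0)
    neighbors = (1.0 - sim) <= cutoff

    unassigned = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    while unassigned.any():
        counts = (neighbors & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        centroid = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbors[centroid] & unassigned)
        if centroid not in members:  # all-zero row can miss self; be safe
            members = np.append(members, centroid)
        labels[members] = cluster
        unassigned[members] = False
        cluster += 1
    return ClusterSet({ids[i]: int(labels[i]) for i in range(n)},
                      "butina", {"cutoff": cutoff})


def butina_split(clusters: ClusterSet, k: int = 7) -> FoldAssignment:
    """Pack whole Butina clusters into k folds, balancing fold sizes.

    Largest cluster first into the currently smallest fold; when clusters are
    small relative to n the folds come out near-equal.
    """
    groups = [(str(ci), members) for ci, members in enumerate(clusters.clusters())]
    return _pack_groups(groups, k, "butina", None,
                        dict(clusters.params, packing="greedy-balanced"))


def umap_cluster_split(fps: list[np.ndarray], n_clusters: int = 7,
                       umap_params: dict | None = None, seed: int = 0,
                       ids: list[str] | None = None) -> FoldAssignment:
    """UMAP embedding + agglomerative clustering; the clusters are the folds.

    Fingerprints are embedded with UMAP (Jaccard metric on the bit vectors by
    default) and the embedding is cut into ``n_clusters`` by Ward-linkage
    agglomerative clustering.  Fold index = cluster index, so fold sizes are
    uneven by construction.  Reproducible under a fixed seed.

    Default UMAP settings: n_neighbors=15, min_dist=0.1, n_components=2;
    override any of them (plus ``linkage``) through ``umap_params``.
    """
    import umap
    from sklearn.cluster import AgglomerativeClustering

    n = len(fps)
    if ids is None:
        ids = [str(i) for i in range(n)]
    if n_clusters < 1 or n_clusters > n:
        raise SplitError(f"n_clusters={n_clusters} invalid for {n} molecules")
    params = {"n_neighbors": 15, "min_dist": 0.1, "n_components": 2,
              "metric": "jaccard", "linkage": "ward"}
    params.update(umap_params or {})
    X = np.asarray(np.stack(fps), dtype=np.float32)
    if n_clusters == 1:
        fold_of = {i: 0 for i in ids}
        return FoldAssignment("umap", 1, seed, fold_of, params).validate()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about seeded single-threading
        embedding = umap.UMAP(
            n_neighbors=min(params["n_neighbors"], n - 1),
            min_dist=params["min_dist"],
            n_components=params["n_components"],
            metric=params["metric"],
            random_state=seed,
        ).fit_transform(X)
    labels = AgglomerativeClustering(
        n_clusters=n_clusters, linkage=params["linkage"]).fit_predict(embedding)
    fold_of = {ids[i]: int(labels[i]) for i in range(n)}
    return FoldAssignment("umap", n_clusters, seed, fold_of, params).validate()


def restrict_to_dataset(master: FoldAssignment,
                        labeled_ids: set[str]) -> FoldAssignment:
    """Induce the master partition on a dataset's labeled subset.

    Fold indices are preserved, so the same molecule sits in the same fold in
    every dataset restricted from one master split.  Labeled IDs absent from
    the master are logged and dropped.  A fold can come out empty; the
    evaluation layer skips empty test folds.
    """
    unknown = labeled_ids - master.fold_of.keys()
    if unknown:
        warnings.warn(
            f"{len(unknown)} labeled IDs not in master split were dropped")
    fold_of = {i: f for i, f in master.fold_of.items() if i in labeled_ids}
    if not fold_of:
        raise SplitError("no_labeled_molecules: empty intersection with master")
    return FoldAssignment(master.strategy, master.k, master.seed,
                          fold_of, dict(master.params)).validate()
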