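"""Split strategies: partition property, grouping invariants, Butina oracle."""

import numpy as np
import pytest

import realsplit as rs
from realsplit.chem import MoleculeRecord
from realsplit.splits import SplitError


def brute_force_sphere_exclusion(fps, cutoff):
    """Independent sphere-exclusion oracle using explicit set arithmetic.

    Recomputes, at every step, each unassigned molecule's count of
    unassigned neighbors (Tanimoto distance <= cutoff), takes the molecule
    with the highest count (lowest index on ties) as centroid and absorbs
    its unassigned neighbors.
    """
    n = len(fps)
    neighbors = [
        {j for j in range(n)
         if 1.0 - rs.tanimoto(fps[i], fps[j]) <= cutoff}
        for i in range(n)
    ]
    unassigned = set(range(n))
    labels = {}
    cluster = 0
    while unassigned:
        best = max(sorted(unassigned),
                   key=lambda i: (len(neighbors[i] & unassigned), -i))
        members = (neighbors[best] & unassigned) | {best}
        for m in members:
            labels[m] = cluster
        unassigned -= members
        cluster += 1
    return labels


class TestRandomSplit:
    def test_near_equal_fold_sizes(self):
        a = rs.random_split([str(i) for i in range(10)], k=3, seed=0)
        assert sorted(a.fold_sizes(), reverse=True) == [4, 3, 3]

    def test_singleton_folds_when_k_equals_n(self):
        a = rs.random_split(list("abcdefg"), k=7, seed=1)
        assert a.fold_sizes() == [1] * 7

    def test_seed_determinism_and_variation(self):
        ids = [str(i) for i in range(100)]
        assert rs.random_split(ids, 7, 3).fold_of == rs.random_split(ids, 7, 3).fold_of
        assert rs.random_split(ids, 7, 3).fold_of != rs.random_split(ids, 7, 4).fold_of

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(SplitError):
            rs.random_split(["a", "b"], k=3, seed=0)


class TestScaffoldSplit:
    def _records(self, smiles_list):
        recs = []
        for i, smi in enumerate(smiles_list):
            rec = rs.standardize(smi, mol_id=f"m{i}")
            rs.murcko_scaffold(rec)
            recs.append(rec)
        return recs

    def test_shared_scaffold_shared_fold(self):
        recs = self._records(["Cc1ccccc1", "CCc1ccccc1", "Cc1ccncc1",
                              "CCc1ccncc1", "C1CCCCC1", "CCC"])
        a = rs.scaffold_split(recs, k=3)
        by_scaffold = {}
        for r in recs:
            by_scaffold.setdefault(r.scaffold, set()).add(a.fold_of[r.id])
        for folds in by_scaffold.values():
            assert len(folds) == 1

    def test_k1_puts_everything_in_fold_zero(self):
        recs = self._records(["Cc1ccccc1", "C1CCCCC1"])
        a = rs.scaffold_split(recs, k=1)
        assert set(a.fold_of.values()) == {0}

    def test_greedy_packing_of_known_group_sizes(self):
        # groups {5,4,3,2,2,1} into k=3: largest-first into smallest fold
        sizes = [5, 4, 3, 2, 2, 1]
        smiles = ["c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1",
                  "C1CCCCC1", "C1CCNCC1"]
        subs = ["C", "CC", "CCC", "CCCC", "CCCCC"]
        lib = []
        for core, size in zip(smiles, sizes):
            for s in subs[:size]:
                lib.append(f"{s}{core}" if core[0] == "c" else f"{s}{core}")
        recs = self._records(lib)
        a = rs.scaffold_split(recs, k=3)
        assert sorted(a.fold_sizes(), reverse=True) == [6, 6, 5]

    def test_insufficient_groups_error(self):
        recs = self._records(["Cc1ccccc1", "CCc1ccccc1"])
        with pytest.raises(SplitError, match="insufficient_groups"):
            rs.scaffold_split(recs, k=3)

    def test_hash_order_is_stable_per_scaffold(self):
        recs = self._records(["Cc1ccccc1", "CCc1ccccc1", "Cc1ccncc1",
                              "C1CCCCC1", "CC1CCCCC1", "c1ccoc1", "c1ccsc1"])
        a = rs.scaffold_split(recs, k=2, strategy_order="hash")
        b = rs.scaffold_split(list(reversed(recs)), k=2, strategy_order="hash")
        assert a.fold_of == b.fold_of


class TestButina:
    def test_identical_molecules_single_cluster(self):
        fp = np.zeros(32, dtype=np.uint8)
        fp[[3, 7, 11]] = 1
        cs = rs.butina_cluster([fp.copy() for _ in range(5)], cutoff=0.4)
        assert set(cs.labels.values()) == {0}

    def test_disjoint_fingerprints_all_singletons(self):
        fps = [np.eye(16, dtype=np.uint8)[i] for i in range(8)]
        cs = rs.butina_cluster(fps, cutoff=0.4)
        assert cs.n_singletons() == 8

    def test_planted_hub_becomes_first_centroid(self):
        # hub = bits {0..4}; satellite j drops bit j and adds bit 10+j:
        # hub-satellite similarity 4/6 (distance 1/3 <= 0.4), satellite
        # pairs share 3 bits of 7 (distance 0.57 > 0.4); plus one loner
        hub = np.zeros(24, dtype=np.uint8); hub[[0, 1, 2, 3, 4]] = 1
        sats = []
        for j in range(4):
            s = hub.copy()
            s[j] = 0
            s[10 + j] = 1
            sats.append(s)
        loner = np.zeros(24, dtype=np.uint8); loner[[20, 21, 22]] = 1
        fps = [sats[0], hub, *sats[1:], loner]
        cs = rs.butina_cluster(fps, cutoff=0.4)
        expected = brute_force_sphere_exclusion(fps, 0.4)
        assert {int(k): v for k, v in cs.labels.items()} == expected
        assert cs.labels["1"] == 0  # hub's cluster formed first
        assert cs.labels["5"] != 0  # loner excluded

    def test_matches_bruteforce_oracle_on_small_inputs(self, rng):
        for _ in range(150):
            n = int(rng.integers(1, 11))
            nbits = int(rng.integers(4, 24))
            fps = [(rng.random(nbits) < 0.35).astype(np.uint8) for _ in range(n)]
            cutoff = float(rng.uniform(0.1, 0.9))
            got = rs.butina_cluster(fps, cutoff=cutoff).labels
            want = brute_force_sphere_exclusion(fps, cutoff)
            assert {int(k): v for k, v in got.items()} == want

    def test_every_member_within_cutoff_of_centroid(self, rng):
        fps = [(rng.random(64) < 0.3).astype(np.uint8) for _ in range(40)]
        cs = rs.butina_cluster(fps, cutoff=0.5)
        # centroid of cluster c = first selected; recover from oracle order
        labels = brute_force_sphere_exclusion(fps, 0.5)
        assert {int(k): v for k, v in cs.labels.items()} == labels

    def test_butina_split_greedy_packing(self):
        labels = {}
        mol = 0
        for ci, size in enumerate([5, 4, 3, 2, 2, 1]):
            for _ in range(size):
                labels[f"m{mol}"] = ci
                mol += 1
        cs = rs.ClusterSet(labels, "butina")
        a = rs.butina_split(cs, k=3)
        assert sorted(a.fold_sizes(), reverse=True) == [6, 6, 5]
        for members in cs.clusters():
            assert len({a.fold_of[m] for m in members}) == 1

    def test_butina_split_insufficient_clusters(self):
        cs = rs.ClusterSet({"a": 0, "b": 0}, "butina")
        with pytest.raises(SplitError, match="insufficient_groups"):
            rs.butina_split(cs, k=3)


class TestUmapSplit:
    def test_folds_are_clusters_and_seed_reproducible(self, library, fps2048):
        records, truth = library
        ids = [r.id for r in records]
        fps = [fps2048[i] for i in ids]
        a = rs.umap_cluster_split(fps, n_clusters=7, seed=11, ids=ids)
        b = rs.umap_cluster_split(fps, n_clusters=7, seed=11, ids=ids)
        assert a.fold_of == b.fold_of
        assert set(a.fold_of.values()) == set(range(7))

    def test_recovers_planted_chemotype_families(self, library, master_splits):
        from sklearn.metrics import adjusted_rand_score

        records, truth = library
        for seed, assignment in master_splits["umap"].items():
            fams = [truth.family_of[r.id] for r in records]
            got = [assignment.fold_of[r.id] for r in records]
            assert adjusted_rand_score(fams, got) > 0.9

    def test_single_cluster_single_fold(self):
        fps = [np.eye(8, dtype=np.uint8)[i % 8] for i in range(10)]
        a = rs.umap_cluster_split(fps, n_clusters=1, seed=0)
        assert set(a.fold_of.values()) == {0}

    def test_too_many_clusters_rejected(self):
        with pytest.raises(SplitError):
            rs.umap_cluster_split([np.ones(8, dtype=np.uint8)] * 3, n_clusters=5)


class TestRestrictToDataset:
    def test_identity_restriction(self):
        master = rs.random_split(list("abcdef"), k=3, seed=0)
        sub = rs.restrict_to_dataset(master, set("abcdef"))
        assert sub.fold_of == master.fold_of

    def test_fold_indices_preserved(self):
        master = rs.random_split([str(i) for i in range(50)], k=5, seed=2)
        labeled = {str(i) for i in range(0, 50, 3)}
        sub = rs.restrict_to_dataset(master, labeled)
        assert set(sub.fold_of) == labeled
        for mol_id in labeled:
            assert sub.fold_of[mol_id] == master.fold_of[mol_id]

    def test_empty_intersection_is_error(self):
        master = rs.random_split(list("abc"), k=1, seed=0)
        with pytest.raises(SplitError, match="no_labeled_molecules"):
            rs.restrict_to_dataset(master, {"zzz"})

    def test_missing_fold_allowed_in_restriction(self):
        master = rs.FoldAssignment("random", 3, 0,
                                   {"a": 0, "b": 1, "c": 2}).validate()
        sub = rs.restrict_to_dataset(master, {"a", "b"})
        assert 2 not in sub.fold_of.values()


class TestShiftOrdering:
    def test_umap_split_shifts_more_than_random_every_seed(self, shift_means):
        """Cluster-held-out test folds must look less like training data."""
        wide = shift_means.pivot(index="seed", columns="split",
                                 values="mean_max_sim")
        assert (wide["umap"] < wide["random"] - 0.05).all()


def test_fold_assignment_roundtrip(tmp_path):
    import realsplit.io as rs_io

    a = rs.random_split([f"m{i}" for i in range(20)], k=4, seed=9)
    path = tmp_path / "folds.tsv"
    rs_io.write_fold_assignment(a, path)
    b = rs_io.read_fold_assignment(path)
    assert b.fold_of == a.fold_of
    assert (b.strategy, b.k, b.seed) == (a.strategy, a.k, a.seed)
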