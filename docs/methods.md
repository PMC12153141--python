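# Methods

## The problem

Benchmarks for activity-prediction models in virtual screening (VS) are only
as honest as their train/test splits. A random split leaves close structural
analogs of every test molecule in the training set, so models are rewarded
for memorizing local neighborhoods rather than generalizing. Scaffold
(Bemis-Murcko) splits and Butina sphere-exclusion splits are widely treated
as the rigorous alternative, yet both still admit strong train/test
similarity: two molecules can have formally different scaffolds while
differing by a single atom or a linker carbon. `realsplit` implements four
splitting strategies of increasing realism, a merged cross-validation
harness, VS-aligned metrics, and the diagnostics to measure how much shift a
split actually induces.

## Splitting strategies

All strategies produce a k-fold partition (default k = 7) of a master
molecule set; per-dataset splits are induced by restriction so a molecule
keeps its fold index in every dataset.

* **random** — seeded shuffle dealt into folds whose sizes differ by at most
  one.
* **scaffold** — molecules grouped by the canonical SMILES of their
  Bemis-Murcko framework (acyclic molecules form one extra group). Whole
  groups go to folds. Group-to-fold order is not canonical in the
  literature; the default is greedy balancing (largest group into the
  currently smallest fold), with a stable-hash alternative whose assignment
  is independent of the rest of the library. Both are approximations and the
  choice is recorded in the assignment's provenance.
* **butina** — sphere exclusion on Tanimoto distances over 2048-bit
  radius-2 Morgan fingerprints. Two molecules are neighbors at distance
  ≤ cutoff (default 0.4; the value is a convention, not a law, and is
  exposed as a parameter). The unassigned molecule with the most unassigned
  neighbors is repeatedly chosen as a centroid and absorbs its unassigned
  neighbors, so every member lies within the cutoff of its centroid. Ties
  break toward the lowest input index, making the procedure deterministic
  given input order. Clusters are packed whole into folds, largest first
  into the smallest fold.
* **umap** — fingerprints are embedded with UMAP (Jaccard metric,
  n_neighbors = 15, min_dist = 0.1, 2 components, seeded) and the embedding
  is cut into k clusters by Ward-linkage agglomerative clustering. The
  clusters *are* the folds: sizes are uneven by construction, because
  chemical space is. All parameters are recorded in the assignment.

Fold indices are 0-based in code and 1-based in serialized reports.

## Evaluation

Models are trained as pGI50 regressors and scored the way a prospective
screen uses them ("dual regression-classification"):

* measured activities are binarized at pGI50 > 6 (1 µM); exactly 6 is
  inactive;
* predictions are binarized by rank: the top k = 100 predicted molecules
  are positives — a fixed purchasing budget, not a value cutoff. Boundary
  ties break by input order; test sets smaller than k make everything
  positive with a warning rather than failing, so small restricted datasets
  still evaluate;
* hit rate = 100·TP/(TP+FP) is the primary metric (NaN if no predicted
  positives, which top-k cannot produce); MCC uses the convention 0 when a
  marginal is empty; ROC AUC is the rank-based Mann-Whitney estimator with
  midrank ties, NaN on single-class labels; RMSE is standard.

Cross-validation **merges** the out-of-fold predictions from all k folds and
computes each metric once on the pooled table, instead of averaging k
per-fold metrics. With uneven fold sizes and heterogeneous active counts the
two differ (a unit test demonstrates this on a constructed case), and
merging keeps the top-100 budget meaningful.

Model comparisons use two-sided paired Wilcoxon signed-rank tests over
(dataset, seed) evaluation records — the standard nonparametric paired test
matching a boxplot-over-records design; the test statistic choice is a
package decision since different fields default differently, and it is
configurable. Identical record sets short-circuit to p = 1 (zero
differences carry no evidence). P-values map to the annotation scale
ns / * / ** / *** / **** at 5×10⁻², 1×10⁻², 1×10⁻³, 1×10⁻⁴. No
multiple-testing correction is applied by default; Holm step-down is
available as a flag.

The benchmark manifest counts one trained model per (learner, dataset,
fold, seed); the split strategies are an axis of the evaluation design
recorded on the manifest but not multiplied into the model count.

## Features

Baseline learners consume a 263-length vector: a 256-bit radius-2 Morgan
fingerprint concatenated with 7 physicochemical descriptors — molecular
weight, Wildman-Crippen logP, TPSA, H-bond donors, H-bond acceptors,
rotatable bonds, ring count, in that order. The panel is a package decision:
a standard druglikeness set of exactly seven descriptors; any fixed
seven-descriptor panel serves the same role and the identity of each
position is documented in `chem.DESCRIPTOR_NAMES`. Similarity diagnostics
always use a separate 2048-bit radius-2 fingerprint regardless of the model
feature size.

Standardization strips salts by keeping the fragment with the most heavy
atoms (ties by lexicographic canonical SMILES), removes explicit hydrogens,
and emits canonical SMILES; failures become typed rejection records, never
silent drops. Tanimoto similarity of two all-zero fingerprints is defined
as 1.0 (two featureless molecules are treated as alike, not undefined).

SMILES augmentation produces the canonical string plus up to n (default 10)
atom-order-randomized spellings rooted at random atoms, deduplicated, all
re-canonicalizing to the same structure — up to 11 strings per molecule,
fewer for small or symmetric molecules.

## Diagnostics

The shift statistic is, for each test molecule, the maximum Tanimoto
similarity to any training molecule; its mean over a test set summarizes how
much of the test chemistry the model has effectively seen. It is monotone in
the training set. Clustering quality uses silhouette (Jaccard distance on
fingerprints, Euclidean on embeddings), Davies-Bouldin and
Calinski-Harabasz (both centroid-based, hence Euclidean on the points as
given), plus a singleton count; degenerate labelings (one cluster, all
singletons) yield NaN with a warning. Activity histograms bin pGI50 into
[4,5), [5,6), [6,7), [7,∞) with an underflow bucket for values below the
censoring floor.

## The synthetic benchmark library

The generator builds a desk-scale library with the statistical structure the
framework assumes, so every claim is testable without external data:

* **7 chemotype families**, each grown from a structurally distinct
  ring-system core (anthracene, phenothiazine, N-methylcarbazole,
  fluorenone, xanthene, naphthalimide, spiroundecane) carrying a fixed
  family marker group drawn from a vocabulary disjoint from the substituent
  panel — keeping between-family Tanimoto similarity near 0.1.
* **Five attachment series per family**: a plain methyl, plus two pairs of
  family-specific rings joined through a one- or two-carbon linker. The
  linker-length variants ("twins", e.g. benzyl next to phenethyl) have
  different Bemis-Murcko scaffolds but fingerprint similarity around 0.6 —
  the deliberate stress case in which the scaffold split separates
  near-identical molecules while sphere exclusion at the 0.4 cutoff keeps
  them together. Each series is crossed with 12 small substituents;
  within-series similarity is ≈ 0.7.
* **Activity model**: pGI50 = dataset baseline + family effect (sd 0.8,
  redrawn per dataset) + attachment-series effect (sd 0.5, per dataset) +
  substituent effect (sd 0.2, global) + molecule noise (sd 0.4), clamped to
  [4, 8]. The baseline is centered so that ≈ 15% of uncensored values
  exceed the activity threshold of 6, echoing VS class imbalance; clamping
  reproduces the pile-up of floor-censored values observed in real
  growth-inhibition panels. Labels are dropped at random to 88.8% coverage
  per dataset. Defaults: 7 × 50 molecules, 10 datasets, seed-deterministic.

Because activity is driven by family and series effects that are redrawn per
dataset, a learner can predict a test molecule well only if its chemotype is
represented in training — precisely the leakage the cluster-based splits
remove. On this library the four strategies order as intended: mean
max-Tanimoto shift random > scaffold > butina ≫ umap, and the forest
learner's median merged hit rate drops from ~35% under random splits to
single digits under the UMAP split.

What the generator does **not** emulate: real medicinal-chemistry diversity
(hundreds of thousands of scaffolds, not 35), activity cliffs (the noise
model is smooth in structure), inter-dataset correlation structure between
cell lines of the same tissue, and assay artifacts beyond range censoring.
Passing tests on this library therefore demonstrate that the machinery
measures what it claims under the similarity principle; they do not predict
absolute performance numbers on real panels.

## Problem sizes and numerical choices

The shipped test suite runs the full benchmark grid at 7 families × 50
molecules × 10 datasets × 5 seeds with the 100-tree forest learner under
all four strategies — about 200 merged cross-validations — which keeps a
complete run on one CPU in the ten-minute range. Determinism: every
stochastic step (shuffles, UMAP, forest, augmentation, the generator) takes
an explicit seed; scaffold and Butina splits are deterministic given input
order with lowest-index tie-breaks. Degenerate inputs are errors where they
would corrupt accounting (duplicate predictions, fold overlap, empty
intersections) and warnings where evaluation remains meaningful (test sets
smaller than the top-k budget, single-class AUC, labeled IDs missing from a
master split).

## Known limitations

* The greedy group-packing used for scaffold and Butina splits balances
  sizes but is only one of several defensible orders; published fold sizes
  from other groups will not reproduce exactly.
* UMAP embeddings are seed-reproducible but not stable across library
  versions; provenance is recorded in every assignment for this reason.
* The external-model adapter runs one subprocess per fold and passes
  features as text tables; it is meant for benchmarking pre-trained
  models, not for training loops with GPU scheduling.
* Hit rate with a fixed k compares models at one operating point; k is
  configurable but results at different k are not comparable to each other.
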