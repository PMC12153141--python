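"""Molecule standardization, featurization, scaffolds and SMILES augmentation.

Feature convention used by the baseline learners: a 256-bit radius-2 Morgan
(circular) fingerprint concatenated with 7 physicochemical descriptors, giving
a 263-length vector per molecule.  Chemical-similarity diagnostics use a
separate, longer 2048-bit radius-2 fingerprint; both lengths are parameters
with these defaults at their respective call sites.

The 7 descriptors, in fixed order (see :data:`DESCRIPTOR_NAMES`): molecular
weight, Wildman-Crippen logP, topological polar surface area, hydrogen-bond
donor count, hydrogen-bond acceptor count, rotatable-bond count, ring count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

#: Names of the physicochemical descriptors, in the order they appear in the
#: descriptor vector and in the tail of the 263-length feature vector.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "mol_weight",
    "clogp",
    "tpsa",
    "h_bond_donors",
    "h_bond_acceptors",
    "rotatable_bonds",
    "ring_count",
)

_DESCRIPTOR_FUNCS = (
    Descriptors.MolWt,
    Descriptors.MolLogP,
    Descriptors.TPSA,
    Descriptors.NumHDonors,
    Descriptors.NumHAcceptors,
    Descriptors.NumRotatableBonds,
    Descriptors.RingCount,
)

#: Default fingerprint length for model features.
N_BITS_FEATURES = 256
#: Default fingerprint length for similarity diagnostics.
N_BITS_SIMILARITY = 2048
#: Morgan radius used everywhere.
FP_RADIUS = 2
#: Total model feature vector length.
N_FEATURES = N_BITS_FEATURES + len(DESCRIPTOR_NAMES)


@dataclass
class Rejection:
    """A molecule that failed standardization, with a machine-readable reason."""

    id: str
    raw_smiles: str
    reason: str  # "parse_error" | "empty_after_standardization" | "descriptor_error"

    def __str__(self) -> str:  # line-oriented rejection-log format
        return f"{self.id}\t{self.reason}\t{self.raw_smiles}"


@dataclass
class MoleculeRecord:
    """One standardized molecule with its features and per-dataset labels.

    ``labels`` maps dataset identifier (e.g. a cell-line name) to measured
    pGI50 (negative base-10 log of the molar GI50; higher = more potent).
    """

    id: str
    smiles_canonical: str
    fp_features: np.ndarray | None = None     # 256 bits, radius 2
    fp_similarity: np.ndarray | None = None   # 2048 bits, radius 2
    descriptors: np.ndarray | None = None     # 7 reals
    scaffold: str | None = None               # "" for acyclic molecules
    labels: dict[str, float] = field(default_factory=dict)

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles_canonical)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol | None:
    """Keep the fragment with the most heavy atoms (salt stripping).

    Ties broken by lexicographically smallest canonical SMILES so the result
    never depends on fragment order in the input string.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        return None
    return max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def standardize(raw_smiles: str, mol_id: str = "") -> MoleculeRecord | Rejection:
    """Standardize a raw SMILES: strip salts, drop explicit H, canonicalize.

    Returns a :class:`MoleculeRecord` carrying only the canonical SMILES (call
    :func:`featurize` / :func:`murcko_scaffold` to fill the rest), or a
    :class:`Rejection` with reason ``parse_error`` for unparsable input and
    ``empty_after_standardization`` when nothing survives salt stripping.
    Deterministic.
    """
    if not raw_smiles or not raw_smiles.strip():
        return Rejection(mol_id, raw_smiles, "parse_error")
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        return Rejection(mol_id, raw_smiles, "parse_error")
    mol = _largest_fragment(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        return Rejection(mol_id, raw_smiles, "empty_after_standardization")
    mol = Chem.RemoveHs(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return Rejection(mol_id, raw_smiles, "parse_error")
    canonical = Chem.MolToSmiles(mol)
    if not canonical:
        return Rejection(mol_id, raw_smiles, "empty_after_standardization")
    return MoleculeRecord(id=mol_id, smiles_canonical=canonical)


def fingerprint(record: MoleculeRecord, n_bits: int = N_BITS_SIMILARITY,
                radius: int = FP_RADIUS) -> np.ndarray:
    """Morgan fingerprint of a standardized molecule as a uint8 0/1 vector."""
    if n_bits <= 0:
        raise ValueError(f"n_bits must be positive, got {n_bits}")
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.array(gen.GetFingerprint(record.mol()), dtype=np.uint8)


def compute_descriptors(record: MoleculeRecord) -> np.ndarray:
    """The 7 physicochemical descriptors in :data:`DESCRIPTOR_NAMES` order."""
    mol = record.mol()
    if mol is None:
        raise ValueError(f"cannot parse canonical SMILES for molecule {record.id!r}")
    return np.array([f(mol) for f in _DESCRIPTOR_FUNCS], dtype=float)


def featurize(record: MoleculeRecord) -> np.ndarray:
    """263-length model feature vector: [256-bit fingerprint || 7 descriptors].

    Fills ``record.fp_features`` and ``record.descriptors`` as a side effect.
    Canonicalization-invariant: any SMILES form of the same molecule gives an
    identical vector.
    """
    if record.fp_features is None:
        record.fp_features = fingerprint(record, n_bits=N_BITS_FEATURES)
    if record.descriptors is None:
        record.descriptors = compute_descriptors(record)
    return np.concatenate([record.fp_features.astype(float), record.descriptors])


def murcko_scaffold(record: MoleculeRecord) -> str:
    """Canonical SMILES of the Bemis-Murcko framework; "" for acyclic molecules.

    The framework keeps ring systems and the linkers connecting them, removing
    side chains.  Idempotent: a framework is its own framework.
    """
    scaffold = MurckoScaffold.MurckoScaffoldSmiles(
        smiles=record.smiles_canonical, includeChirality=False)
    record.scaffold = scaffold
    return scaffold


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity |a AND b| / |a OR b| of two bit vectors.

    Returns 1.0 when both vectors are all-zero: two featureless molecules are
    treated as maximally similar rather than undefined.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def augment_smiles(record: MoleculeRecord, n_random: int = 10,
                   seed: int = 0) -> list[str]:
    """Canonical SMILES plus up to ``n_random`` atom-order-randomized variants.

    Randomization permutes the atom numbering with a seeded generator and
    writes the molecule non-canonically, so each variant spells the same
    structure differently; duplicates are removed while preserving first
    occurrence.  The list therefore has between 1 and ``n_random + 1`` entries
    (small or highly symmetric molecules admit fewer distinct spellings), and
    every entry re-canonicalizes to ``record.smiles_canonical``.
    """
    mol = record.mol()
    rng = np.random.default_rng(seed)
    variants = [record.smiles_canonical]
    seen = {record.smiles_canonical}
    for _ in range(n_random):
        order = rng.permutation(mol.GetNumAtoms()).tolist()
        shuffled = Chem.RenumberAtoms(mol, order)
        # rooting at a random atom varies the traversal start as well
        root = int(rng.integers(shuffled.GetNumAtoms()))
        smi = Chem.MolToSmiles(shuffled, canonical=False, rootedAtAtom=root)
        if smi not in seen:
            seen.add(smi)
            variants.append(smi)
    return variants
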