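"""Synthetic molecule libraries with the statistical structure of screening data.

The generator emulates, at desk scale, the structure of a multi-cell-line
growth-inhibition panel: a shared pool of molecules organized into chemotype
families, several "cell line" datasets that each label only a fraction of
the pool, pGI50 values censored to [4, 8] at the assay concentration range,
and the similarity principle — structurally similar molecules receive
correlated activities by construction.

Each family grows from one distinct ring-system core decorated with a
family-specific marker group.  Within a family, molecules carry one of five
ring attachments — none (a methyl), or one of two family-specific rings
joined through a one- or two-carbon linker — crossed with a panel of small
substituents.  The linker-length variants ("twins", e.g. a benzyl next to a
phenethyl) are the deliberate stress case for scaffold-based splitting:
their Bemis-Murcko scaffolds differ while their fingerprints are nearly
identical, the same trap that benzene/pyridine scaffold pairs set in real
libraries.  Sphere-exclusion clustering at the default 0.4 distance cutoff
groups twins together; the scaffold split separates them.

Activity model per molecule i in dataset d:

    pGI50(i, d) = baseline(d) + family_effect(family(i), d)
                  + series_effect(family(i), attachment_class(i), d)
                  + substituent_effect(sub(i)) + noise(i, d)

clamped to [censor_low, censor_high].  Family and series effects are
redrawn per dataset, so each cell line has its own potent chemotypes —
signal a model can only learn when the chemotype is represented in its
training fold, which is exactly what the cluster-based splits withhold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chem import MoleculeRecord, Rejection, standardize

#: Seven chemotype families: (core template with two substitution sites and a
#: fixed family marker group, four ring attachments = two linker-twin pairs).
#: Cores are structurally distinct ring systems; attachment rings are
#: family-specific, so between-family Tanimoto similarity stays low.
FAMILY_TEMPLATES: tuple[tuple[str, tuple[str, str, str, str]], ...] = (
    ("c1cc({r1})c2cc3cc({r2})c(SC)cc3cc2c1",              # anthracene
     ("Cc5ccccc5", "CCc5ccccc5", "Cc5ccncc5", "CCc5ccncc5")),
    ("c1cc({r1})c2c(c1)Nc1cc({r2})c(C(C)=O)cc1S2",        # phenothiazine
     ("CC5CCCCC5", "CCC5CCCCC5", "CC5CCNCC5", "CCC5CCNCC5")),
    ("c1cc({r1})c2c(c1)n(C)c1cc({r2})ccc21",              # N-methylcarbazole
     ("Cc5ccco5", "CCc5ccco5", "Cc5cccs5", "CCc5cccs5")),
    ("O=C1c2cc({r1})c(OC(F)F)cc2-c2ccc({r2})cc21",        # fluorenone
     ("CC5CCOCC5", "CCC5CCOCC5", "CC5CCSCC5", "CCC5CCSCC5")),
    ("c1cc({r1})c2c(c1)Cc1cc({r2})c(S(C)(=O)=O)cc1O2",    # xanthene
     ("Cc5cscn5", "CCc5cscn5", "Cc5cocn5", "CCc5cocn5")),
    ("O=C1N({r1})C(=O)c2cc3cc({r2})c(C(=O)NC)cc3cc21",    # naphthalimide
     ("CC5CCC5", "CCC5CCC5", "CC5CCCC5", "CCC5CCCC5")),
    ("C1CCC2(CC1)CC({r1})C({r2})CC2",                     # spiroundecane
     ("Cc5cccnc5", "CCc5cccnc5", "Cc5ccccn5", "CCc5ccccn5")),
)

#: Attachment placed at r1 when a molecule carries no ring attachment.
PLAIN_ATTACHMENT = "C"

#: Small substituents enumerated at the second site (never empty: the
#: template parentheses require a branch).
SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "O", "OC", "N", "F", "Cl", "C#N", "C(F)(F)F", "C(C)C",
    "CO", "NC",
)


def _attachments(twins: tuple[str, str, str, str]) -> list[tuple[str, int]]:
    """(attachment SMILES, class) list: class 0 = plain, 1/2 = the twin pairs."""
    return [(PLAIN_ATTACHMENT, 0), (twins[0], 1), (twins[1], 1),
            (twins[2], 2), (twins[3], 2)]


@dataclass
class SyntheticLibrarySpec:
    """Parameters of the synthetic library and activity model.

    Defaults give 7 families x 50 molecules scored on 10 datasets with 88.8%
    label coverage, roughly 10-20% actives at the pGI50 > 6 threshold, and
    censoring at 4 and 8 — the shape of a real growth-inhibition panel at
    desk scale.
    """

    n_families: int = 7
    molecules_per_family: int = 50
    n_datasets: int = 10
    label_coverage: float = 0.888
    family_effect_sd: float = 0.8
    series_effect_sd: float = 0.5
    substituent_effect_sd: float = 0.2
    molecule_noise_sd: float = 0.4
    active_fraction_target: float = 0.15
    censor_low: float = 4.0
    censor_high: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_families, self.molecules_per_family, self.n_datasets) < 1:
            raise ValueError("counts must be positive")
        if not (0 < self.label_coverage <= 1):
            raise ValueError("label_coverage must be in (0, 1]")
        if self.censor_low >= self.censor_high:
            raise ValueError("censor_low must be below censor_high")
        if self.n_families > len(FAMILY_TEMPLATES):
            raise ValueError(
                f"only {len(FAMILY_TEMPLATES)} family templates available")

    def dataset_names(self) -> list[str]:
        return [f"CL{d:02d}" for d in range(self.n_datasets)]

    def total_sd(self) -> float:
        """Standard deviation of one pGI50 before censoring."""
        return float(np.sqrt(self.family_effect_sd ** 2
                             + self.series_effect_sd ** 2
                             + self.substituent_effect_sd ** 2
                             + self.molecule_noise_sd ** 2))


@dataclass
class GroundTruth:
    """Hidden generative state kept alongside the library for tests."""

    family_of: dict[str, int]
    class_of: dict[str, int]                       # attachment class 0/1/2
    attachment_of: dict[str, str]
    substituent_of: dict[str, str]
    baseline: dict[str, float] = field(default_factory=dict)
    family_effect: dict[str, list[float]] = field(default_factory=dict)
    series_effect: dict[str, list[list[float]]] = field(default_factory=dict)
    substituent_effect: dict[str, float] = field(default_factory=dict)


def generate_library(spec: SyntheticLibrarySpec,
                     ) -> tuple[list[MoleculeRecord], GroundTruth]:
    """Build the molecule pool by combinatorial substitution of the templates.

    Within a family, (attachment, substituent) pairs are enumerated in a
    seeded random order and any duplicate canonical structure is dropped, so
    every returned molecule is unique, valid and standardized.  Raises when
    the combinatorics cannot supply ``molecules_per_family`` unique
    molecules.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[MoleculeRecord] = []
    truth = GroundTruth({}, {}, {}, {})
    seen_smiles: set[str] = set()
    for fam in range(spec.n_families):
        core, twins = FAMILY_TEMPLATES[fam]
        combos = list(itertools.product(_attachments(twins), SUBSTITUENTS))
        order = rng.permutation(len(combos))
        made = 0
        for idx in order:
            if made == spec.molecules_per_family:
                break
            (attachment, cls), sub = combos[idx]
            mol_id = f"F{fam}_{made:03d}"
            rec = standardize(core.format(r1=attachment, r2=sub), mol_id=mol_id)
            if isinstance(rec, Rejection) or rec.smiles_canonical in seen_smiles:
                continue
            seen_smiles.add(rec.smiles_canonical)
            records.append(rec)
            truth.family_of[mol_id] = fam
            truth.class_of[mol_id] = cls
            truth.attachment_of[mol_id] = attachment
            truth.substituent_of[mol_id] = sub
            made += 1
        if made < spec.molecules_per_family:
            raise ValueError(
                f"family {fam}: only {made} unique molecules available for "
                f"requested {spec.molecules_per_family}")
    return records, truth


def assign_activities(records: list[MoleculeRecord], truth: GroundTruth,
                      spec: SyntheticLibrarySpec) -> GroundTruth:
    """Draw per-dataset pGI50 labels into ``record.labels`` in place.

    The dataset baseline is centered so that, before censoring, the expected
    active fraction at pGI50 > 6 matches ``active_fraction_target`` given
    the variance components.  Labels are then dropped at random to the
    requested coverage.  Deterministic under the spec seed; the label stream
    is separate from the structure stream so the same library can be
    relabeled.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_classes = 3
    baseline_center = (6.0 - stats.norm.ppf(1 - spec.active_fraction_target)
                       * spec.total_sd())
    truth.substituent_effect = {
        s: float(rng.normal(0, spec.substituent_effect_sd)) for s in SUBSTITUENTS}
    for dataset in spec.dataset_names():
        baseline = float(rng.normal(baseline_center, 0.1))
        fam_eff = rng.normal(0, spec.family_effect_sd, size=spec.n_families)
        ser_eff = rng.normal(0, spec.series_effect_sd,
                             size=(spec.n_families, n_classes))
        truth.baseline[dataset] = baseline
        truth.family_effect[dataset] = fam_eff.tolist()
        truth.series_effect[dataset] = ser_eff.tolist()
        keep = rng.random(len(records)) < spec.label_coverage
        noise = rng.normal(0, spec.molecule_noise_sd, size=len(records))
        for i, rec in enumerate(records):
            if not keep[i]:
                continue
            fam = truth.family_of[rec.id]
            cls = truth.class_of[rec.id]
            value = (baseline + fam_eff[fam] + ser_eff[fam, cls]
                     + truth.substituent_effect[truth.substituent_of[rec.id]]
                     + noise[i])
            rec.labels[dataset] = float(
                np.clip(value, spec.censor_low, spec.censor_high))
    return truth


def make_benchmark_library(spec: SyntheticLibrarySpec | None = None,
                           ) -> tuple[list[MoleculeRecord], GroundTruth]:
    """Generate structures and labels in one call with the default spec."""
    spec = spec or SyntheticLibrarySpec()
    records, truth = generate_library(spec)
    assign_activities(records, truth, spec)
    return records, truth
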