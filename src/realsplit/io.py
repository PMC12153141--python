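"""Reading and writing the delimited-text formats used across the package.

All tables are plain TSV/CSV handled by pandas; fold assignments get a JSON
sidecar carrying strategy, parameters and seed so they round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .chem import MoleculeRecord, Rejection, standardize


def read_activity_table(path: str | Path, sep: str = "\t",
                        id_col: str = "id", smiles_col: str = "smiles",
                        ) -> tuple[list[MoleculeRecord], list[Rejection]]:
    """Load a per-cell-line activity table.

    Expected columns: ``id``, ``smiles``, then one numeric pGI50 column per
    dataset (missing determinations left blank).  Every SMILES goes through
    :func:`realsplit.chem.standardize`; failures are returned as rejection
    records, never silently dropped.
    """
    df = pd.read_csv(path, sep=sep)
    dataset_cols = [c for c in df.columns if c not in (id_col, smiles_col)]
    records: list[MoleculeRecord] = []
    rejections: list[Rejection] = []
    for row in df.itertuples(index=False):
        out = standardize(getattr(row, smiles_col), mol_id=str(getattr(row, id_col)))
        if isinstance(out, Rejection):
            rejections.append(out)
            continue
        for col in dataset_cols:
            val = getattr(row, col)
            if pd.notna(val):
                out.labels[col] = float(val)
        records.append(out)
    return records, rejections


def read_smiles_file(path: str | Path) -> tuple[list[MoleculeRecord], list[Rejection]]:
    """Read a plain SMILES file: one molecule per line, optional ID after whitespace."""
    records: list[MoleculeRecord] = []
    rejections: list[Rejection] = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"mol_{i}"
        out = standardize(smiles, mol_id=mol_id)
        (rejections if isinstance(out, Rejection) else records).append(out)
    return records, rejections


def write_molecule_table(records: list[MoleculeRecord], path: str | Path,
                         sep: str = "\t") -> None:
    """Write standardized molecules (id, canonical SMILES, scaffold, labels)."""
    datasets = sorted({d for r in records for d in r.labels})
    rows = []
    for r in records:
        row = {"id": r.id, "smiles": r.smiles_canonical, "scaffold": r.scaffold or ""}
        for d in datasets:
            row[d] = r.labels.get(d)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_rejection_log(rejections: list[Rejection], path: str | Path) -> None:
    Path(path).write_text("".join(f"{r}\n" for r in rejections))


def write_fold_assignment(assignment, path: str | Path, sep: str = "\t") -> None:
    """Serialize a FoldAssignment as (id, fold) TSV + JSON sidecar of provenance.

    Fold indices are written 1-based for human consumption and shifted back on
    read; internally folds are always 0-based.
    """
    path = Path(path)
    df = pd.DataFrame(
        {"id": list(assignment.fold_of), "fold": [f + 1 for f in assignment.fold_of.values()]}
    )
    df.to_csv(path, sep=sep, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"strategy": assignment.strategy, "k": assignment.k,
         "seed": assignment.seed, "params": assignment.params}, indent=2))


def read_fold_assignment(path: str | Path, sep: str = "\t"):
    from .splits import FoldAssignment

    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype={"id": str})
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    fold_of = {str(i): int(f) - 1 for i, f in zip(df["id"], df["fold"])}
    return FoldAssignment(strategy=meta["strategy"], k=meta["k"],
                          seed=meta["seed"], fold_of=fold_of,
                          params=meta.get("params", {}))
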