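"""Activity-table loading, cleaning, pIC50 transform, folds and batches.

The input is a delimited table with one row per drug/activity record
(drug id, SMILES, IC50, optional cell-line/tissue metadata). Cleaning
drops rows with missing or unparseable SMILES and rows whose IC50 is
missing, zero or negative — the transform to pIC50 = -log10(IC50) is
undefined there. IC50 is assumed to be in micromolar; the unit only
shifts pIC50 by an additive constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .chem_graph import MolecularGraph, SmilesParseError, smiles_to_graph
from .model import GraphBatch

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityRecord",
    "DropReport",
    "FoldAssignment",
    "load_activity_table",
    "clean_records",
    "to_pic50",
    "kfold_split",
    "make_batches",
]

DEFAULT_COLUMNS = {"drug_id": "drug_id", "smiles": "smiles", "ic50": "ic50"}
OPTIONAL_COLUMNS = {"cell_line": "cell_line", "tissue": "tissue"}


@dataclass
class ActivityRecord:
    """One row of the activity table; pic50 is derived after cleaning."""

    drug_id: str
    smiles: str | None
    ic50: float | None
    pic50: float | None = None
    cell_line: str | None = None
    tissue: str | None = None


@dataclass
class DropReport:
    """Counts of records removed per cleaning rule."""

    missing_smiles: int = 0
    invalid_smiles: int = 0
    missing_ic50: int = 0
    nonpositive_ic50: int = 0

    @property
    def total(self) -> int:
        return (self.missing_smiles + self.invalid_smiles
                + self.missing_ic50 + self.nonpositive_ic50)


@dataclass
class FoldAssignment:
    """k-fold partition of n samples: fold_of[i] in 0..k-1."""

    fold_of: np.ndarray
    k: int
    seed: int

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, val_idx) for one fold."""
        val = np.flatnonzero(self.fold_of == fold)
        train = np.flatnonzero(self.fold_of != fold)
        return train, val


def load_activity_table(path, column_map: dict[str, str] | None = None,
                        sep: str = ",") -> list[ActivityRecord]:
    """Read a delimited activity table into records.

    ``column_map`` maps the logical names drug_id/smiles/ic50 (and
    optionally cell_line/tissue) to the file's column headers. Missing
    cells become ``None``, never zero; a non-numeric IC50 cell is logged
    and treated as missing.
    """
    cmap = dict(DEFAULT_COLUMNS)
    cmap.update(OPTIONAL_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    mandatory = [cmap["drug_id"], cmap["smiles"], cmap["ic50"]]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"mandatory columns absent from {path}: {missing}")

    records = []
    for i, row in df.iterrows():
        smiles = row[cmap["smiles"]].strip() or None
        raw_ic50 = row[cmap["ic50"]].strip()
        ic50: float | None
        if not raw_ic50:
            ic50 = None
        else:
            try:
                ic50 = float(raw_ic50)
            except ValueError:
                logger.warning("row %d: non-numeric IC50 %r treated as missing",
                               i, raw_ic50)
                ic50 = None
        records.append(ActivityRecord(
            drug_id=row[cmap["drug_id"]],
            smiles=smiles,
            ic50=ic50,
            cell_line=(row[cmap["cell_line"]].strip() or None)
            if cmap["cell_line"] in df.columns else None,
            tissue=(row[cmap["tissue"]].strip() or None)
            if cmap["tissue"] in df.columns else None,
        ))
    return records


def to_pic50(ic50: float, unit_scale: float = 1.0) -> float:
    """pIC50 = -log10(IC50 * unit_scale); requires IC50 > 0.

    Higher pIC50 means stronger inhibitory activity. ``unit_scale``
    converts the table's unit to the reference unit (default 1: the
    table is taken at face value, assumed micromolar).
    """
    if ic50 is None or not np.isfinite(ic50) or ic50 <= 0:
        raise ValueError(f"pIC50 undefined for IC50 = {ic50!r}")
    return float(-np.log10(ic50 * unit_scale))


def clean_records(records, unit_scale: float = 1.0
                  ) -> tuple[list[ActivityRecord], DropReport]:
    """Apply the cleaning rules and attach pIC50 to the survivors.

    Rules: drop missing SMILES, unparseable SMILES, missing IC50, and
    zero/negative IC50. Idempotent: cleaning already-clean records is
    the identity.
    """
    kept: list[ActivityRecord] = []
    report = DropReport()
    for rec in records:
        if rec.smiles is None:
            report.missing_smiles += 1
            continue
        if rec.ic50 is None or not np.isfinite(rec.ic50):
            report.missing_ic50 += 1
            continue
        if rec.ic50 <= 0:
            report.nonpositive_ic50 += 1
            continue
        try:
            smiles_to_graph(rec.smiles)
        except SmilesParseError:
            report.invalid_smiles += 1
            continue
        kept.append(ActivityRecord(
            drug_id=rec.drug_id, smiles=rec.smiles, ic50=rec.ic50,
            pic50=to_pic50(rec.ic50, unit_scale),
            cell_line=rec.cell_line, tissue=rec.tissue,
        ))
    return kept, report


def kfold_split(n: int, k: int = 5, seed: int = 42,
                groups=None) -> FoldAssignment:
    """Shuffled k-fold assignment with near-equal fold sizes.

    For k=5 each validation fold holds 20% of the samples (n/5 +- 1).
    ``groups`` optionally assigns whole groups (e.g. one drug's records)
    to a single fold to prevent leakage.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    fold_of = np.empty(n, dtype=np.int64)
    if groups is None:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        for fold, (_, val) in enumerate(splitter.split(np.arange(n))):
            fold_of[val] = fold
    else:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        if uniq.size < k:
            raise ValueError("fewer groups than folds")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(uniq)
        for fold, chunk in enumerate(np.array_split(perm, k)):
            fold_of[np.isin(groups, chunk)] = fold
    return FoldAssignment(fold_of=fold_of, k=k, seed=seed)


def make_batches(graphs: list[MolecularGraph], targets, batch_size: int,
                 shuffle: bool = False,
                 rng: np.random.Generator | int | None = None
                 ) -> list[GraphBatch]:
    """Partition a dataset into GraphBatch objects for one epoch.

    Every sample appears exactly once; with ``shuffle`` off the original
    order is preserved.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    targets = np.asarray(targets, dtype=np.float64)
    if len(graphs) != targets.shape[0]:
        raise ValueError("graphs and targets misaligned")
    order = np.arange(len(graphs))
    if shuffle:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        order = rng.permutation(order)
    batches = []
    for start in range(0, len(graphs), batch_size):
        idx = order[start:start + batch_size]
        batches.append(GraphBatch.from_graphs(
            [graphs[i] for i in idx], targets[idx]))
    return batches
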