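"""Feature tables and pre-analysis transformations.

A :class:`FeatureTable` is one subject-by-variable numeric block (e.g. a
behavioral-health battery, cortical thickness / subcortical volumes, or
functional-connectivity features), keyed by subject ID and optionally carrying
a categorical group label per subject (e.g. ``"younger"`` / ``"older"``).

The transformations here are the ones applied before any canonical
correlation analysis:

* residualizing selected columns on a nuisance covariate (e.g. adjusting
  subcortical volumes for intracranial volume),
* dropping variables with low inter-subject variability or with a
  near-duplicate elsewhere in the block (|Pearson r| above a threshold),
* z-standardizing both blocks after aligning rows by subject ID.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "StandardizedPair",
    "RemovalRecord",
    "read_feature_table",
    "write_table",
    "covariate_adjust",
    "filter_variables",
    "standardize_pair",
]


class TableError(ValueError):
    """Malformed or inconsistent feature-table input."""


@dataclass
class FeatureTable:
    """One subject x variable numeric block.

    Parameters
    ----------
    subject_ids : sequence of str
        Unique, ordered subject identifiers (one per row of ``values``).
    variable_names : sequence of str
        Unique, ordered variable names (one per column of ``values``).
    values : ndarray of shape (n_subjects, n_variables)
        Finite numeric matrix.
    block_label : str
        Free-text label for the block (``"behavioral"``, ``"sMRI"``, ...).
    group_labels : ndarray of str, optional
        Per-subject categorical label, aligned with ``subject_ids``.
    """

    subject_ids: list[str]
    variable_names: list[str]
    values: np.ndarray
    block_label: str = ""
    group_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.variable_names = [str(v) for v in self.variable_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TableError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.subject_ids):
            raise TableError(
                f"{n} rows but {len(self.subject_ids)} subject IDs"
            )
        if p != len(self.variable_names):
            raise TableError(
                f"{p} columns but {len(self.variable_names)} variable names"
            )
        if len(set(self.subject_ids)) != n:
            dupes = _duplicates(self.subject_ids)
            raise TableError(f"duplicate subject IDs: {dupes}")
        if len(set(self.variable_names)) != p:
            dupes = _duplicates(self.variable_names)
            raise TableError(f"duplicate variable names: {dupes}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise TableError(
                "non-finite value at subject "
                f"{self.subject_ids[i]!r}, variable {self.variable_names[j]!r}"
            )
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels, dtype=object)
            if len(self.group_labels) != n:
                raise TableError("group_labels length does not match rows")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self, id_column: str = "subject_id",
                     group_column: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, id_column, self.subject_ids)
        if group_column is not None and self.group_labels is not None:
            df.insert(1, group_column, self.group_labels)
        return df

    def select(self, variables: Sequence[str]) -> "FeatureTable":
        """Return a copy restricted to ``variables`` (kept in given order)."""
        idx = [self.variable_names.index(v) for v in variables]
        return dataclasses.replace(
            self, variable_names=list(variables), values=self.values[:, idx]
        )

    def take_subjects(self, rows: Sequence[int]) -> "FeatureTable":
        rows = list(rows)
        g = None if self.group_labels is None else self.group_labels[rows]
        return dataclasses.replace(
            self,
            subject_ids=[self.subject_ids[i] for i in rows],
            values=self.values[rows],
            group_labels=g,
        )


@dataclass
class StandardizedPair:
    """Row-aligned, z-scored behavioral (X) and imaging (Y) blocks.

    Every column of ``X`` and ``Y`` has mean 0 and sample (n-1) standard
    deviation 1; rows of the two matrices refer to the same subjects in the
    same order.
    """

    X: np.ndarray
    Y: np.ndarray
    names_x: list[str]
    names_y: list[str]
    subject_ids: list[str] = field(default_factory=list)
    group_labels: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class RemovalRecord:
    """One variable dropped by :func:`filter_variables`."""

    variable: str
    reason: str          # "low_sd" or "high_corr"
    partner: str | None  # retained near-duplicate, for "high_corr"
    statistic: float     # the offending sd or |r|


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for it in items:
        if it in seen and it not in out:
            out.append(it)
        seen.add(it)
    return out


def read_feature_table(path: str | Path, id_column: str = "subject_id",
                       group_column: str | None = None,
                       block_label: str = "",
                       drop_missing_subjects: bool = False) -> FeatureTable:
    """Read a delimited text table (CSV or TSV, header row) into a FeatureTable.

    ``id_column`` supplies subject IDs; ``group_column``, if given, is removed
    from the numeric matrix and stored as per-subject group labels.  A missing
    cell is an error naming the offending subject and variable, unless
    ``drop_missing_subjects`` is set, in which case subjects with any missing
    cell are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if id_column not in df.columns:
        raise TableError(f"ID column {id_column!r} not found in {path.name}")
    ids = df[id_column].astype(str).tolist()
    groups = None
    data = df.drop(columns=[id_column])
    if group_column is not None:
        if group_column not in data.columns:
            raise TableError(
                f"group column {group_column!r} not found in {path.name}")
        groups = data[group_column].astype(str).to_numpy(dtype=object)
        data = data.drop(columns=[group_column])
    numeric = data.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~data.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise TableError(
            f"non-numeric cell at subject {ids[i]!r}, "
            f"variable {data.columns[j]!r}: {data.iat[i, j]!r}"
        )
    if numeric.isna().to_numpy().any():
        if drop_missing_subjects:
            keep = ~numeric.isna().any(axis=1).to_numpy()
            ids = [s for s, k in zip(ids, keep) if k]
            numeric = numeric.loc[keep]
            if groups is not None:
                groups = groups[keep]
        else:
            i, j = np.argwhere(numeric.isna().to_numpy())[0]
            raise TableError(
                f"missing value at subject {ids[i]!r}, "
                f"variable {numeric.columns[j]!r}"
            )
    return FeatureTable(
        subject_ids=ids,
        variable_names=list(numeric.columns),
        values=numeric.to_numpy(dtype=float),
        block_label=block_label,
        group_labels=groups,
    )


def write_table(table: FeatureTable, path: str | Path,
                id_column: str = "subject_id",
                group_column: str | None = None) -> None:
    """Write a FeatureTable as CSV (``.csv``) or TSV (``.tsv``/``.tab``)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    if group_column is None and table.group_labels is not None:
        group_column = "group"
    table.to_dataframe(id_column, group_column).to_csv(
        path, sep=sep, index=False)


def covariate_adjust(table: FeatureTable, covariate: np.ndarray,
                     columns: Sequence[str] | None = None) -> FeatureTable:
    """Residualize selected columns on ``[intercept, covariate]`` by OLS.

    Used for intracranial-volume adjustment of volumetric features; any
    per-subject nuisance covariate works.  Unselected columns are returned
    bit-identical.
    """
    covariate = np.asarray(covariate, dtype=float)
    if covariate.shape != (table.n_subjects,):
        raise TableError(
            f"covariate length {covariate.size} != {table.n_subjects} subjects")
    if np.ptp(covariate) == 0:
        raise TableError("covariate is constant; residualization is singular")
    if columns is None:
        columns = table.variable_names
    missing = [c for c in columns if c not in table.variable_names]
    if missing:
        raise TableError(f"unknown columns: {missing}")
    design = np.column_stack([np.ones_like(covariate), covariate])
    values = table.values.copy()
    idx = [table.variable_names.index(c) for c in columns]
    beta, *_ = np.linalg.lstsq(design, values[:, idx], rcond=None)
    values[:, idx] = values[:, idx] - design @ beta
    return dataclasses.replace(table, values=values)


def filter_variables(table: FeatureTable, corr_threshold: float = 0.85,
                     min_sd: float = 0.0
                     ) -> tuple[FeatureTable, list[RemovalRecord]]:
    """Drop low-variability and near-duplicate variables.

    First removes every column whose sample standard deviation falls below
    ``min_sd``.  Then scans the remaining variable pairs in column order and,
    whenever |Pearson r| exceeds ``corr_threshold``, greedily removes the
    *later* column (the earlier one in file order is kept).  The removal log
    records each dropped variable, the reason, the retained partner for
    correlation removals, and the offending statistic.
    """
    if not 0 < corr_threshold <= 1:
        raise ValueError("corr_threshold must be in (0, 1]")
    if min_sd < 0:
        raise ValueError("min_sd must be non-negative")
    log: list[RemovalRecord] = []
    sds = table.values.std(axis=0, ddof=1)
    keep = [i for i in range(table.n_variables) if sds[i] >= min_sd]
    for i in range(table.n_variables):
        if sds[i] < min_sd:
            log.append(RemovalRecord(table.variable_names[i], "low_sd",
                                     None, float(sds[i])))
    if keep:
        sub = table.values[:, keep]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        corr = np.atleast_2d(corr)
        removed = np.zeros(len(keep), dtype=bool)
        for a in range(len(keep)):
            if removed[a]:
                continue
            for b in range(a + 1, len(keep)):
                if removed[b]:
                    continue
                r = corr[a, b]
                if np.isfinite(r) and abs(r) > corr_threshold:
                    removed[b] = True
                    log.append(RemovalRecord(
                        table.variable_names[keep[b]], "high_corr",
                        table.variable_names[keep[a]], float(abs(r))))
        keep = [k for k, r in zip(keep, removed) if not r]
    if not keep:
        raise TableError("variable filter removed every column")
    survivors = [table.variable_names[i] for i in keep]
    return table.select(survivors), log


def removal_log_frame(log: list[RemovalRecord]) -> pd.DataFrame:
    """Removal log as a tidy table (variable, reason, partner, statistic)."""
    return pd.DataFrame(
        [(r.variable, r.reason, r.partner, r.statistic) for r in log],
        columns=["variable", "reason", "partner", "statistic"],
    )


def standardize_pair(behavioral: FeatureTable,
                     imaging: FeatureTable) -> StandardizedPair:
    """Align two blocks by subject ID and z-score every column.

    Columns are centred and scaled by the sample (n-1) standard deviation.
    Rows of the imaging block are reordered to the behavioral block's subject
    order.  A zero-variance column is an error naming the column.
    """
    set_x, set_y = set(behavioral.subject_ids), set(imaging.subject_ids)
    if set_x != set_y:
        only_x = sorted(set_x - set_y)[:5]
        only_y = sorted(set_y - set_x)[:5]
        raise TableError(
            f"subject sets differ (only behavioral: {only_x}, "
            f"only imaging: {only_y})")
    order = [imaging.subject_ids.index(s) for s in behavioral.subject_ids]
    Y = imaging.values[order]
    X = behavioral.values
    for names, M, label in ((behavioral.variable_names, X, behavioral.block_label),
                            (imaging.variable_names, Y, imaging.block_label)):
        sd = M.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [n for n, s in zip(names, sd) if s == 0]
            raise TableError(f"zero-variance column(s) in {label or 'block'}: {bad}")
    return StandardizedPair(
        X=zscore(X),
        Y=zscore(Y),
        names_x=list(behavioral.variable_names),
        names_y=list(imaging.variable_names),
        subject_ids=list(behavioral.subject_ids),
        group_labels=(None if behavioral.group_labels is None
                      else np.asarray(behavioral.group_labels, dtype=object)),
    )


def zscore(M: np.ndarray) -> np.ndarray:
    """Column-wise z-score with the sample (n-1) standard deviation."""
    M = np.asarray(M, dtype=float)
    return (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
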