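"""Reading, standardizing and splitting vocal-feature tables.

The on-disk dialect is the UCI Parkinson's speech table: a comma-separated
file with one header row, a subject-id column, a binary class column
(1 = person with Parkinson's, 0 = healthy control) and several hundred
numeric dysphonia features.  One row is one voice recording; a subject
typically owns three consecutive rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "StandardizationParams",
    "read_feature_table",
    "write_feature_table",
    "check_missing",
    "standardize_fit",
    "standardize_apply",
    "stratified_split",
]


class FeatureTableError(ValueError):
    """Malformed feature table or incompatible operands."""


@dataclass
class FeatureTable:
    """A recordings-by-features matrix with labels and subject identity.

    Parameters
    ----------
    feature_names
        Ordered, unique column names.
    values
        2-D float array, rows are recordings and columns are features.
    labels
        Binary vector, 1 = case (PWP), 0 = healthy control.
    subject_ids
        One identifier per row; repeated recordings share an id.
    group_of
        Optional map from feature name to a feature-family tag
        (baseline / time_frequency / mfcc / wt / vocal_fold / tqwt / ...).
    """

    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    group_of: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FeatureTableError("values must be a 2-D matrix")
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        n, p = self.values.shape
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise FeatureTableError(
                "labels and subject_ids must match the number of rows"
            )
        if len(self.feature_names) != p:
            raise FeatureTableError("feature_names must match the number of columns")
        if len(set(self.feature_names)) != p:
            raise FeatureTableError("feature names must be unique")
        if n and not np.isin(self.labels, (0, 1)).all():
            raise FeatureTableError("labels must be binary (0/1)")
        self.labels = self.labels.astype(int)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take_rows(self, index: np.ndarray) -> "FeatureTable":
        """A new table restricted to the given row indices (order kept)."""
        return FeatureTable(
            feature_names=list(self.feature_names),
            values=self.values[index],
            labels=self.labels[index],
            subject_ids=self.subject_ids[index],
            group_of=self.group_of,
        )

    def select_features(self, mask: np.ndarray) -> "FeatureTable":
        """A new table restricted to the columns where ``mask`` is truthy."""
        mask = np.asarray(mask).astype(bool)
        if mask.shape != (self.n_features,):
            raise FeatureTableError("mask length must equal the feature count")
        names = [n for n, keep in zip(self.feature_names, mask) if keep]
        return FeatureTable(
            feature_names=names,
            values=self.values[:, mask],
            labels=self.labels,
            subject_ids=self.subject_ids,
            group_of=self.group_of,
        )

    def to_dataframe(
        self, label_column: str = "class", id_column: str = "id"
    ) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, id_column, self.subject_ids)
        df[label_column] = self.labels
        return df


def read_feature_table(
    path,
    label_column: str = "class",
    id_column: str = "id",
) -> FeatureTable:
    """Load a feature table from CSV.

    Every column other than ``label_column`` and ``id_column`` must parse
    as a real number; an unparseable or empty cell is a hard error naming
    the offending row and column (the expected tables have no missing
    values, so absence signals corruption rather than a case for
    imputation).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FeatureTableError(f"empty input file: {path}") from exc
    if df.shape[0] == 0:
        raise FeatureTableError(f"no data rows in {path}")
    for col in (label_column, id_column):
        if col not in df.columns:
            raise KeyError(
                f"required column {col!r} not found in {path} "
                f"(configure label_column/id_column)"
            )
    feature_cols = [c for c in df.columns if c not in (label_column, id_column)]
    values = np.empty((df.shape[0], len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(parsed.isna().to_numpy())
        if bad.size:
            raise FeatureTableError(
                f"non-numeric or missing value at data row {bad[0]}, "
                f"column {col!r}"
            )
        values[:, j] = parsed.to_numpy(dtype=float)
    labels = pd.to_numeric(df[label_column], errors="coerce")
    if labels.isna().any() or not labels.isin((0, 1)).all():
        raise FeatureTableError(f"label column {label_column!r} must be binary 0/1")
    return FeatureTable(
        feature_names=feature_cols,
        values=values,
        labels=labels.to_numpy(dtype=int),
        subject_ids=df[id_column].to_numpy(),
    )


def write_feature_table(
    table: FeatureTable,
    path,
    label_column: str = "class",
    id_column: str = "id",
) -> None:
    """Write the table back in the same CSV dialect ``read_feature_table`` reads."""
    table.to_dataframe(label_column=label_column, id_column=id_column).to_csv(
        path, index=False
    )


def check_missing(table: FeatureTable) -> int:
    """Count NaN cells in the feature matrix.

    Parsing already rejects missing cells, so a table read from disk always
    reports 0; the operation exists so a pipeline report can state the
    missing-value audit explicitly.
    """
    return int(np.isnan(table.values).sum())


@dataclass
class StandardizationParams:
    """Per-feature location/scale for z-score standardization, x' = (x - mu) / sigma.

    ``sigma`` follows the population convention (divide by n).
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape:
            raise FeatureTableError("mu and sigma must have equal length")
        if (self.sigma < 0).any():
            raise FeatureTableError("sigma must be non-negative")


def standardize_fit(table: FeatureTable) -> StandardizationParams:
    """Column means and population standard deviations of the feature matrix."""
    if table.n_rows < 1:
        raise FeatureTableError("cannot fit standardization on an empty table")
    return StandardizationParams(
        mu=table.values.mean(axis=0),
        sigma=table.values.std(axis=0, ddof=0),
    )


def standardize_apply(
    table: FeatureTable, params: StandardizationParams
) -> FeatureTable:
    """z-score the feature matrix; constant columns (sigma == 0) map to 0."""
    if params.mu.shape != (table.n_features,):
        raise FeatureTableError(
            f"params dimension {params.mu.shape[0]} != feature count "
            f"{table.n_features}"
        )
    sigma = np.where(params.sigma == 0, 1.0, params.sigma)
    z = (table.values - params.mu) / sigma
    z[:, params.sigma == 0] = 0.0
    return FeatureTable(
        feature_names=list(table.feature_names),
        values=z,
        labels=table.labels,
        subject_ids=table.subject_ids,
        group_of=table.group_of,
    )


def _apportion_test_counts(class_sizes: np.ndarray, fraction: float) -> np.ndarray:
    """Largest-remainder apportionment of test rows across classes.

    Totals hit round(n * fraction) exactly, so a 756-row table at 0.25
    always yields 189 test rows, 141 of them positive when 564 rows are.
    """
    total = int(round(class_sizes.sum() * fraction))
    ideal = class_sizes * fraction
    base = np.floor(ideal).astype(int)
    remainder = ideal - base
    short = total - base.sum()
    # hand the leftover seats to the largest remainders; ties go to the
    # smaller class (its proportion has more at stake), then to the lower
    # class index, for determinism
    order = np.lexsort((np.arange(len(class_sizes)), class_sizes, -remainder))
    counts = base.copy()
    for k in order[: max(short, 0)]:
        counts[k] += 1
    return counts


def stratified_split(
    table: FeatureTable,
    test_fraction: float,
    seed: int,
    group_by_subject: bool = False,
) -> tuple[FeatureTable, FeatureTable]:
    """Seeded stratified partition into train and test tables.

    The default stratifies individual recordings, mirroring the common
    protocol for this table even though one subject owns several rows;
    ``group_by_subject=True`` instead keeps all recordings of a subject on
    one side (leakage-aware alternative), stratifying subjects by label.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = table.labels
    classes = np.unique(labels)
    if classes.size < 2:
        raise FeatureTableError("stratified split needs both classes present")

    test_rows: list[np.ndarray] = []
    if group_by_subject:
        subj_ids, first_idx = np.unique(table.subject_ids, return_index=True)
        subj_labels = labels[first_idx]
        sizes = np.array([(subj_labels == c).sum() for c in classes])
        counts = _apportion_test_counts(sizes, test_fraction)
        for c, k in zip(classes, counts):
            members = subj_ids[subj_labels == c]
            if k == 0 or k == members.size:
                raise FeatureTableError(
                    f"test_fraction {test_fraction} empties class {c} on one side"
                )
            chosen = rng.permutation(members)[:k]
            test_rows.append(np.flatnonzero(np.isin(table.subject_ids, chosen)))
    else:
        sizes = np.array([(labels == c).sum() for c in classes])
        if (sizes < 2).any():
            raise FeatureTableError("each class needs at least 2 rows to split")
        counts = _apportion_test_counts(sizes, test_fraction)
        for c, k in zip(classes, counts):
            members = np.flatnonzero(labels == c)
            if k == 0 or k == members.size:
                raise FeatureTableError(
                    f"test_fraction {test_fraction} empties class {c} on one side"
                )
            test_rows.append(rng.permutation(members)[:k])

    test_index = np.sort(np.concatenate(test_rows))
    train_index = np.setdiff1d(np.arange(table.n_rows), test_index)
    return table.take_rows(train_index), table.take_rows(test_index)
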