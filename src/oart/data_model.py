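"""Feature tables, min-max normalization, and one-class train/test splitting.

A :class:`FeatureTable` is the universal input of the package: a dense
``n_samples x m_features`` matrix of real values, with opaque sample ids,
feature names, per-feature category tags (e.g. ``ROI`` / ``dose`` /
``machine``) and optional labels in ``{-1, +1}`` (−1 acceptable,
+1 unacceptable).  Missing features are represented by zeros upstream, never
by NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LABEL_ACCEPTABLE",
    "LABEL_UNACCEPTABLE",
    "FeatureTable",
    "ScalingParams",
    "OneClassSplit",
    "read_feature_table",
    "write_feature_table",
    "minmax_fit",
    "minmax_apply",
    "split_one_class",
]

LABEL_ACCEPTABLE = -1
LABEL_UNACCEPTABLE = +1

#: default category assigned when no per-feature annotation is given
DEFAULT_CATEGORY = "all"


@dataclass
class FeatureTable:
    """samples × features matrix with ids, names, categories and labels."""

    values: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]
    feature_category: list[str] | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        n, m = self.values.shape
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite feature value at row {bad[0]}, column {bad[1]}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        self.feature_names = [str(s) for s in self.feature_names]
        if len(self.feature_names) != m:
            raise ValueError("feature_names length does not match number of columns")
        if self.feature_category is None:
            self.feature_category = [DEFAULT_CATEGORY] * m
        else:
            self.feature_category = [str(c) for c in self.feature_category]
        if len(self.feature_category) != m:
            raise ValueError("feature_category length does not match number of columns")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels length does not match number of rows")
            bad = ~np.isin(self.labels, (LABEL_ACCEPTABLE, LABEL_UNACCEPTABLE))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"label of sample {self.sample_ids[row]!r} (row {row}) is "
                    f"{self.labels[row]!r}; labels must be -1 or +1"
                )
            self.labels = self.labels.astype(int)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def m_features(self) -> int:
        return self.values.shape[1]

    def select_rows(self, indices: np.ndarray) -> "FeatureTable":
        """Sub-table with the given rows (order preserved as given)."""
        indices = np.asarray(indices, dtype=int)
        return FeatureTable(
            values=self.values[indices],
            sample_ids=[self.sample_ids[i] for i in indices],
            feature_names=list(self.feature_names),
            feature_category=list(self.feature_category),
            labels=None if self.labels is None else self.labels[indices],
        )

    def reorder_features(self, names: list[str]) -> "FeatureTable":
        """Align columns to ``names`` (by feature name, not position)."""
        pos = {n: i for i, n in enumerate(self.feature_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise ValueError(f"table is missing features: {missing[:5]}")
        order = [pos[n] for n in names]
        return FeatureTable(
            values=self.values[:, order],
            sample_ids=list(self.sample_ids),
            feature_names=list(names),
            feature_category=[self.feature_category[i] for i in order],
            labels=self.labels,
        )

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "sample_id", self.sample_ids)
        if self.labels is not None:
            df[label_column] = self.labels
        return df


@dataclass
class ScalingParams:
    """Per-feature min-max scaling parameters, fitted on training samples only."""

    minimum: np.ndarray
    maximum: np.ndarray
    degenerate_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != self.maximum.shape or self.minimum.ndim != 1:
            raise ValueError("minimum/maximum must be matching 1-D vectors")
        if (self.maximum < self.minimum).any():
            raise ValueError("maximum < minimum for some feature")
        self.degenerate_mask = self.maximum == self.minimum

    @property
    def m_features(self) -> int:
        return self.minimum.shape[0]


@dataclass
class OneClassSplit:
    """Acceptable-only training table and mixed held-out test table."""

    train: FeatureTable
    test: FeatureTable
    seed: int
    train_indices: np.ndarray
    test_indices: np.ndarray


def read_feature_table(
    path,
    fmt: str | None = None,
    label_column: str | None = "label",
    category_path=None,
) -> FeatureTable:
    """Read a CSV/TSV feature table (rows = samples, columns = features).

    The header row holds feature names; an optional ``sample_id`` column holds
    ids and ``label_column`` (pass ``None`` for unlabeled scoring input) holds
    −1/+1 labels.  ``category_path`` is an optional sidecar CSV mapping
    ``feature_name`` to ``category``.
    """
    sep = _separator(path, fmt)
    df = pd.read_csv(path, sep=sep)
    if "sample_id" in df.columns:
        sample_ids = [str(s) for s in df.pop("sample_id")]
    else:
        sample_ids = [str(i) for i in range(len(df))]
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"missing label column {label_column!r}")
        labels = df.pop(label_column).to_numpy()
    feature_names = [str(c) for c in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric feature value at row {sample_ids[r]!r} "
            f"(line {r}), column {feature_names[c]!r}"
        )
    categories = None
    if category_path is not None:
        cat_df = pd.read_csv(category_path)
        mapping = dict(zip(cat_df["feature_name"].astype(str), cat_df["category"].astype(str)))
        categories = [mapping.get(n, DEFAULT_CATEGORY) for n in feature_names]
    return FeatureTable(
        values=numeric.to_numpy(dtype=float),
        sample_ids=sample_ids,
        feature_names=feature_names,
        feature_category=categories,
        labels=labels,
    )


def write_feature_table(
    table: FeatureTable, path, fmt: str | None = None, category_path=None
) -> None:
    """Write a table as CSV/TSV, optionally with a category sidecar CSV."""
    sep = _separator(path, fmt)
    table.to_dataframe().to_csv(path, sep=sep, index=False)
    if category_path is not None:
        pd.DataFrame(
            {"feature_name": table.feature_names, "category": table.feature_category}
        ).to_csv(category_path, index=False)


def _separator(path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unknown table format {fmt!r}")
    return "\t" if fmt == "tsv" else ","


def minmax_fit(train: FeatureTable | np.ndarray) -> ScalingParams:
    """Columnwise extrema of the training samples."""
    values = train.values if isinstance(train, FeatureTable) else np.asarray(train, float)
    if values.size == 0:
        raise ValueError("cannot fit scaling on an empty table")
    return ScalingParams(minimum=values.min(axis=0), maximum=values.max(axis=0))


def minmax_apply(table, params: ScalingParams):
    """Scale to ``(x − min) / (max − min)`` per feature.

    Training columns map exactly onto [0,1].  Test values outside the training
    range are NOT clipped (anomalous deviations must survive normalization).
    Degenerate (constant) training columns use denominator 1, so training
    values map to 0 while a shifted test value keeps its offset ``x − min``.
    """
    is_table = isinstance(table, FeatureTable)
    values = table.values if is_table else np.asarray(table, float)
    if values.shape[-1] != params.m_features:
        raise ValueError(
            f"dimension mismatch: {values.shape[-1]} features vs "
            f"{params.m_features} scaling parameters"
        )
    denom = np.where(params.degenerate_mask, 1.0, params.maximum - params.minimum)
    scaled = (values - params.minimum) / denom
    if not is_table:
        return scaled
    return FeatureTable(
        values=scaled,
        sample_ids=list(table.sample_ids),
        feature_names=list(table.feature_names),
        feature_category=list(table.feature_category),
        labels=table.labels,
    )


def split_one_class(
    table: FeatureTable, train_fraction: float = 0.8, seed: int = 0
) -> OneClassSplit:
    """One-class split: train on acceptable plans only, test on the rest.

    ``floor(train_fraction * n_acceptable)`` acceptable samples go to training
    (uniform without replacement, seeded); the remaining acceptable samples
    plus every unacceptable sample form the test set.
    """
    if table.labels is None:
        raise ValueError("split_one_class requires a labeled table")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    acceptable = np.flatnonzero(table.labels == LABEL_ACCEPTABLE)
    if acceptable.size == 0:
        raise ValueError("no acceptable (-1) samples to train on")
    if acceptable.size < 2:
        raise ValueError("need at least 2 acceptable samples to split")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(train_fraction * acceptable.size))
    chosen = rng.choice(acceptable, size=n_train, replace=False)
    train_idx = np.sort(chosen)
    in_train = np.zeros(table.n_samples, dtype=bool)
    in_train[train_idx] = True
    test_idx = np.flatnonzero(~in_train)
    return OneClassSplit(
        train=table.select_rows(train_idx),
        test=table.select_rows(test_idx),
        seed=seed,
        train_indices=train_idx,
        test_indices=test_idx,
    )
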