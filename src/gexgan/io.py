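"""Reading, writing, filtering and splitting expression tables.

File dialect: the expression matrix is delimited text with a header row of
gene names and a first column of sample identifiers; the label table has
columns ``sample_id``, ``tissue``, ``condition``.  The delimiter is sniffed
from the extension (``.csv`` comma, anything else tab).
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import (
    DegenerateDataError,
    FormatError,
    LabelingError,
    ParseError,
    StratificationError,
)

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "filter_genes",
    "stratified_split",
]

LABEL_COLUMNS = ("sample_id", "tissue", "condition")


def _sep(path: str) -> str:
    return "," if os.path.splitext(str(path))[1].lower() == ".csv" else "\t"


def read_expression_table(path: str, label_path: str) -> ExpressionDataset:
    """Read a matrix/label file pair into a validated dataset.

    Sample order follows the matrix file.  Raises :class:`LabelingError` if
    any sample is missing from the label table, :class:`FormatError` on
    duplicate ids or gene names, :class:`ParseError` (with row/column
    coordinates) on a non-numeric cell.
    """
    with open(path) as fh:  # pandas mangles duplicate headers; check raw
        header = fh.readline().rstrip("\n").split(_sep(path))[1:]
    if len(set(header)) != len(header):
        dupes = sorted({g for g in header if header.count(g) > 1})
        raise FormatError(f"duplicated gene column name(s): {dupes}")
    raw = pd.read_csv(path, sep=_sep(path), index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicated sample id(s): {dupes}")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        try:
            values[:, j] = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(raw[col], errors="coerce")
            i = int(np.argmax(bad.isna().to_numpy()))
            raise ParseError(
                f"non-numeric value {raw[col].iloc[i]!r} at sample "
                f"{raw.index[i]!r} (row {i}), gene {col!r} (column {j})"
            ) from None

    labels = pd.read_csv(label_path, sep=_sep(label_path), dtype=str)
    missing_cols = [c for c in LABEL_COLUMNS if c not in labels.columns]
    if missing_cols:
        raise FormatError(f"label file lacks column(s) {missing_cols}")
    labels = labels.set_index("sample_id")
    if labels.index.duplicated().any():
        raise FormatError("duplicated sample id(s) in label file")
    absent = [s for s in raw.index if s not in labels.index]
    if absent:
        raise LabelingError(f"samples missing from label file: {absent}")
    labels = labels.loc[raw.index]
    return ExpressionDataset(
        values=values,
        sample_ids=raw.index.tolist(),
        gene_names=raw.columns.tolist(),
        tissue=labels["tissue"].to_numpy(),
        condition=labels["condition"].to_numpy(),
    )


def write_expression_table(
    dataset: ExpressionDataset, path: str, label_path: str | None = None
) -> None:
    """Write the matrix (10 significant digits) and, optionally, the labels."""
    dataset.to_frame().to_csv(
        path, sep=_sep(path), float_format="%.10g", index_label="sample_id"
    )
    if label_path is not None:
        dataset.labels_frame().to_csv(
            label_path, sep=_sep(label_path), index_label="sample_id"
        )


def filter_genes(
    dataset: ExpressionDataset, keep: Sequence[str] | set[str]
) -> ExpressionDataset:
    """Restrict columns to ``keep`` (intersection), preserving column order."""
    keep = set(keep)
    if not keep:
        raise DegenerateDataError("empty keep-list")
    cols = [j for j, g in enumerate(dataset.gene_names) if g in keep]
    if not cols:
        raise DegenerateDataError(
            "keep-list shares no gene with the dataset"
        )
    return dataset.subset_genes(cols)


def stratified_split(
    dataset: ExpressionDataset, train_fraction: float, seed: int
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Per-(tissue, condition) random split, deterministic given ``seed``.

    Each stratum contributes ``round(train_fraction * size)`` training
    samples, clamped so both sides keep at least one sample.  Raises
    :class:`StratificationError` on a stratum of size 1.
    """
    if not 0.0 < train_fraction < 1.0:
        raise StratificationError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_rows: list[int] = []
    test_rows: list[int] = []
    for key, rows in dataset.strata().items():
        size = len(rows)
        if size < 2:
            raise StratificationError(
                f"stratum {key} has only {size} sample(s); cannot split"
            )
        n_train = int(round(train_fraction * size))
        n_train = min(max(n_train, 1), size - 1)
        perm = rng.permutation(size)
        train_rows.extend(rows[perm[:n_train]].tolist())
        test_rows.extend(rows[perm[n_train:]].tolist())
    train_rows.sort()
    test_rows.sort()
    return dataset.subset_samples(train_rows), dataset.subset_samples(test_rows)
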