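"""The in-memory expression container shared by every module.

An :class:`ExpressionDataset` is a samples x genes real matrix together with
aligned sample identifiers and two categorical per-sample labels: the tissue
of origin and the condition (``normal`` | ``cancer``).  All downstream
operations (normalization, graph enrichment, GAN training, evaluation)
consume and produce this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError

__all__ = ["ExpressionDataset"]


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with aligned sample labels.

    Parameters
    ----------
    values:
        Real matrix of shape ``(n_samples, n_genes)``; no missing or
        non-finite entries.
    sample_ids:
        Unique sample identifiers, one per row.
    gene_names:
        Unique gene names, one per column.
    tissue, condition:
        Categorical label per sample.  ``condition`` is conventionally
        ``"normal"`` or ``"cancer"`` but any strings are accepted.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_names: list[str]
    tissue: np.ndarray
    condition: np.ndarray
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_names = [str(g) for g in self.gene_names]
        self.tissue = np.asarray(self.tissue, dtype=object)
        self.condition = np.asarray(self.condition, dtype=object)
        if not self._validate:
            return
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise FormatError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.gene_names) != m:
            raise FormatError(
                f"{len(self.gene_names)} gene names for {m} matrix columns"
            )
        if len(self.tissue) != n or len(self.condition) != n:
            raise FormatError("label vectors must have one entry per sample")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample ids")
        if len(set(self.gene_names)) != m:
            raise FormatError("duplicate gene names")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression value at row {bad[0]}, column {bad[1]}"
            )

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def class_labels(self) -> list[tuple[str, str]]:
        """Per-sample (tissue, condition) pairs."""
        return list(zip(self.tissue.tolist(), self.condition.tolist()))

    def strata(self) -> dict[tuple[str, str], np.ndarray]:
        """Row indices grouped by (tissue, condition)."""
        out: dict[tuple[str, str], list[int]] = {}
        for i, key in enumerate(self.class_labels()):
            out.setdefault(key, []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}

    # ------------------------------------------------------------------
    def subset_samples(self, rows: Sequence[int]) -> "ExpressionDataset":
        rows = np.asarray(rows, dtype=int)
        return ExpressionDataset(
            values=self.values[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            gene_names=list(self.gene_names),
            tissue=self.tissue[rows],
            condition=self.condition[rows],
        )

    def subset_genes(self, cols: Sequence[int]) -> "ExpressionDataset":
        cols = np.asarray(cols, dtype=int)
        return ExpressionDataset(
            values=self.values[:, cols],
            sample_ids=list(self.sample_ids),
            gene_names=[self.gene_names[j] for j in cols],
            tissue=self.tissue,
            condition=self.condition,
        )

    def gene_index(self, names: Sequence[str]) -> np.ndarray:
        """Column indices of ``names``; raises on a missing gene."""
        lookup = {g: j for j, g in enumerate(self.gene_names)}
        missing = [g for g in names if g not in lookup]
        if missing:
            raise AlignmentError(f"genes not in dataset: {missing}")
        return np.asarray([lookup[g] for g in names], dtype=int)

    def with_values(self, values: np.ndarray) -> "ExpressionDataset":
        """Same samples/genes/labels, new value matrix."""
        return replace(self, values=np.asarray(values, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.gene_names
        )

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tissue": self.tissue, "condition": self.condition},
            index=self.sample_ids,
        )
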