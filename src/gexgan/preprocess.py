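"""log2 / z-score normalization of raw expression values.

Raw non-negative abundances are mapped to ``(log2(x + pseudocount) - mu_g)
/ sigma_g`` per gene, where ``mu_g`` and ``sigma_g`` are the per-gene mean
and population standard deviation of the log-transformed training data.
Genes with zero variance after the log transform are dropped (a Pearson
correlation is undefined for them) with a warning.  The transform is fitted
on the training split only and applied unchanged elsewhere; its exact
inverse (used before differential-expression style downstream analyses) is
``2**(x * sigma + mu) - pseudocount`` clipped at zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import ExpressionDataset
from .errors import AlignmentError, DegenerateDataError, DomainError

__all__ = [
    "NormalizationStats",
    "ExpressionNormalizer",
    "normalize",
    "denormalize",
]


@dataclass
class NormalizationStats:
    """Fitted per-gene normalization parameters (JSON-serializable)."""

    gene_names: list[str]
    per_gene_mean: np.ndarray
    per_gene_std: np.ndarray
    log_base: int = 2
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.per_gene_mean = np.asarray(self.per_gene_mean, dtype=float)
        self.per_gene_std = np.asarray(self.per_gene_std, dtype=float)
        m = len(self.gene_names)
        if self.per_gene_mean.shape != (m,) or self.per_gene_std.shape != (m,):
            raise AlignmentError("stats vectors must match the gene count")
        if np.any(self.per_gene_std <= 0):
            raise DegenerateDataError("per-gene std must be strictly positive")
        if self.pseudocount < 0:
            raise DomainError("pseudocount must be >= 0")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "gene_names": self.gene_names,
                    "per_gene_mean": self.per_gene_mean.tolist(),
                    "per_gene_std": self.per_gene_std.tolist(),
                    "log_base": self.log_base,
                    "pseudocount": self.pseudocount,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "NormalizationStats":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


class ExpressionNormalizer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping the log2/z-score normalization.

    Operates on :class:`ExpressionDataset`; ``fit`` learns per-gene stats
    (dropping zero-variance genes), ``transform`` applies them and
    ``inverse_transform`` undoes them.
    """

    def __init__(self, log_base: int = 2, pseudocount: float = 1.0):
        self.log_base = log_base
        self.pseudocount = pseudocount

    def fit(self, X: ExpressionDataset, y=None) -> "ExpressionNormalizer":
        if np.any(X.values < 0):
            raise DomainError("raw expression values must be non-negative")
        logged = _logn(X.values + self.pseudocount, self.log_base)
        std = logged.std(axis=0)  # population (divide-by-n) form
        keep = std > 0
        if not np.any(keep):
            raise DegenerateDataError("every gene has zero variance")
        dropped = [g for g, k in zip(X.gene_names, keep) if not k]
        if dropped:
            warnings.warn(
                f"dropping {len(dropped)} zero-variance gene(s): {dropped}",
                stacklevel=2,
            )
        self.stats_ = NormalizationStats(
            gene_names=[g for g, k in zip(X.gene_names, keep) if k],
            per_gene_mean=logged.mean(axis=0)[keep],
            per_gene_std=std[keep],
            log_base=self.log_base,
            pseudocount=self.pseudocount,
        )
        return self

    def transform(self, X: ExpressionDataset) -> ExpressionDataset:
        stats = self.stats_
        X = _aligned(X, stats)
        if np.any(X.values < 0):
            raise DomainError("raw expression values must be non-negative")
        logged = _logn(X.values + stats.pseudocount, stats.log_base)
        return X.with_values(
            (logged - stats.per_gene_mean) / stats.per_gene_std
        )

    def inverse_transform(self, X: ExpressionDataset) -> ExpressionDataset:
        stats = self.stats_
        X = _aligned(X, stats)
        raw = (
            np.power(
                float(stats.log_base),
                X.values * stats.per_gene_std + stats.per_gene_mean,
            )
            - stats.pseudocount
        )
        return X.with_values(np.clip(raw, 0.0, None))


def _logn(x: np.ndarray, base: int) -> np.ndarray:
    if base == 2:
        return np.log2(x)
    return np.log(x) / np.log(float(base))


def _aligned(
    dataset: ExpressionDataset, stats: NormalizationStats
) -> ExpressionDataset:
    """Realign dataset columns to the stats' gene order by name.

    Extra dataset genes (e.g. zero-variance genes dropped at fit time) are
    discarded; a stats gene missing from the dataset is an error.
    """
    if dataset.gene_names == stats.gene_names:
        return dataset
    missing = set(stats.gene_names) - set(dataset.gene_names)
    if missing:
        raise AlignmentError(
            f"dataset lacks gene(s) required by the stats: {sorted(missing)}"
        )
    return dataset.subset_genes(dataset.gene_index(stats.gene_names))


def normalize(
    dataset: ExpressionDataset, log_base: int = 2, pseudocount: float = 1.0
) -> tuple[ExpressionDataset, NormalizationStats]:
    """Fit-and-apply convenience wrapper around :class:`ExpressionNormalizer`."""
    norm = ExpressionNormalizer(log_base=log_base, pseudocount=pseudocount)
    out = norm.fit(dataset).transform(dataset)
    return out, norm.stats_


def denormalize(
    dataset: ExpressionDataset, stats: NormalizationStats
) -> ExpressionDataset:
    """Inverse of :func:`normalize` (realigns columns by gene name)."""
    norm = ExpressionNormalizer(
        log_base=stats.log_base, pseudocount=stats.pseudocount
    )
    norm.stats_ = stats
    return norm.inverse_transform(dataset)
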