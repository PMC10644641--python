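"""Evaluation of generated expression data.

Three complementary views of quality:

* **Correlation-structure similarity** — the gene-gene Pearson matrices
  D^X (real) and D^Z (synthetic) are compared with the ``dist`` statistic:
  the population-form Pearson correlation of their vectorized upper
  triangles, so identical correlation structure scores exactly 1 and an
  affinely negated structure scores -1.
* **Confusion-matrix metrics** — accuracy, precision, recall, F1 and the
  Matthews correlation coefficient from TP/TN/FP/FN counts, with
  zero-denominator metrics reported as missing (None), never as 0.
* **Train-on-synthetic / test-on-real (TSTR)** — a classifier (random
  forest with 200 trees, 5-NN, or a 2x128 ReLU MLP) is fitted on the
  generated samples' normal/cancer labels and evaluated on held-out real
  samples, averaged over seeded repeats (default 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from .dataset import ExpressionDataset
from .errors import AlignmentError, DegenerateDataError, ParameterError

__all__ = [
    "GeneDistanceMatrix",
    "ConfusionCounts",
    "EvalReport",
    "gene_pearson_matrix",
    "dist_score",
    "confusion_metrics",
    "confusion_from_predictions",
    "tstr_classification_eval",
    "key_gene_correlation",
]

POSITIVE_CONDITION = "cancer"


@dataclass
class GeneDistanceMatrix:
    """Symmetric gene x gene Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError("correlation matrix must be square")
        if v.shape[0] != len(self.gene_names):
            raise AlignmentError("gene names must match the matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ParameterError("correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1.0 + 1e-9):
            raise ParameterError("correlations must lie in [-1, 1]")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        i, j = np.triu_indices(self.n_genes, k=1)
        return self.values[i, j]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ParameterError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def gene_pearson_matrix(
    x: np.ndarray | ExpressionDataset,
    gene_names: Sequence[str] | None = None,
    strict: bool = True,
) -> GeneDistanceMatrix:
    """Pairwise Pearson correlation between gene columns, diagonal set to 1.

    ``strict`` raises on a zero-variance gene (naming it); otherwise the
    undefined correlations are reported as 0.
    """
    if isinstance(x, ExpressionDataset):
        gene_names = x.gene_names
        x = x.values
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ParameterError("need a 2-D matrix with at least 2 rows")
    if gene_names is None:
        gene_names = [f"G{j}" for j in range(x.shape[1])]
    if len(gene_names) != x.shape[1]:
        raise AlignmentError("gene names must match the column count")
    std = x.std(axis=0)
    degenerate = np.nonzero(std == 0)[0]
    if degenerate.size and strict:
        names = [gene_names[j] for j in degenerate]
        raise DegenerateDataError(f"zero-variance gene(s): {names}")
    centered = x - x.mean(axis=0)
    safe_std = np.where(std > 0, std, 1.0)
    z = centered / safe_std
    corr = (z.T @ z) / x.shape[0]
    if degenerate.size:
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return GeneDistanceMatrix(values=corr, gene_names=list(gene_names))


def dist_score(dx: GeneDistanceMatrix, dz: GeneDistanceMatrix) -> float:
    """Similarity of two gene-correlation structures in [-1, 1].

    Standardizes each upper triangle by its mean and population standard
    deviation, sums the products over the n(n-1)/2 gene pairs, and divides
    by the number of pairs — i.e. the population Pearson correlation of the
    two upper triangles, so dist(D, D) = 1.
    """
    if dx.gene_names != dz.gene_names:
        raise AlignmentError("the two matrices must share gene set and order")
    if dx.n_genes < 3:
        raise ParameterError("dist requires at least 3 genes")
    ux, uz = dx.upper_triangle(), dz.upper_triangle()
    sx, sz = ux.std(), uz.std()  # population form
    if sx == 0 or sz == 0:
        raise DegenerateDataError(
            "all pairwise correlations equal; dist undefined"
        )
    total = float(np.sum((ux - ux.mean()) / sx * (uz - uz.mean()) / sz))
    return total / ux.size


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, precision, recall, F1 and MCC from confusion counts.

    A metric whose denominator is zero is reported as None.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    accuracy = (tp + tn) / c.total
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else None
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mcc": None if mcc is None else float(mcc),
    }


def confusion_from_predictions(
    y_true: Sequence[str], y_pred: Sequence[str], positive: str = POSITIVE_CONDITION
) -> ConfusionCounts:
    yt = np.asarray([str(v) == positive for v in y_true])
    yp = np.asarray([str(v) == positive for v in y_pred])
    if yt.shape != yp.shape:
        raise AlignmentError("prediction and label vectors must align")
    return ConfusionCounts(
        tp=int(np.sum(yt & yp)),
        tn=int(np.sum(~yt & ~yp)),
        fp=int(np.sum(~yt & yp)),
        fn=int(np.sum(yt & ~yp)),
    )


def _make_classifier(spec: str, seed: int):
    if spec == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if spec == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if spec == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(128, 128),
            activation="relu",
            random_state=seed,
            max_iter=500,
        )
    raise ParameterError(f"unknown classifier spec {spec!r}; use rf|knn|mlp")


def tstr_classification_eval(
    generated: ExpressionDataset,
    real_test: ExpressionDataset,
    classifier_spec: str = "rf",
    repeats: int = 10,
    seed: int = 0,
) -> dict:
    """Train-on-synthetic / test-on-real normal-vs-cancer classification.

    Fits the classifier on ``generated`` (labels = its condition column),
    predicts on ``real_test``, and averages the confusion-matrix metrics
    over ``repeats`` seeded runs.  Undefined metrics are propagated as
    None (excluded from the mean only if undefined in every run).
    """
    if generated.gene_names != real_test.gene_names:
        raise AlignmentError("generated and real data must share genes")
    if repeats < 1:
        raise ParameterError("repeats must be positive")
    if len(set(generated.condition.tolist())) < 2:
        raise DegenerateDataError(
            "generated set contains a single condition class"
        )
    runs = []
    for r in range(repeats):
        clf = _make_classifier(classifier_spec, seed + r)
        clf.fit(generated.values, generated.condition.astype(str))
        pred = clf.predict(real_test.values)
        counts = confusion_from_predictions(real_test.condition, pred)
        runs.append(confusion_metrics(counts))
    means: dict[str, float | None] = {}
    for key in runs[0]:
        vals = [r[key] for r in runs if r[key] is not None]
        means[key] = float(np.mean(vals)) if vals else None
    return {
        "classifier": classifier_spec,
        "repeats": repeats,
        "mean": means,
        "runs": runs,
    }


def key_gene_correlation(
    real: ExpressionDataset,
    generated: ExpressionDataset,
    genes: Sequence[str],
) -> tuple[GeneDistanceMatrix, GeneDistanceMatrix, float]:
    """Pearson submatrices restricted to named key genes, plus the
    element-wise maximum absolute difference between them."""
    real_sub = real.subset_genes(real.gene_index(genes))
    gen_sub = generated.subset_genes(generated.gene_index(genes))
    dx = gene_pearson_matrix(real_sub.values, list(genes), strict=False)
    dz = gene_pearson_matrix(gen_sub.values, list(genes), strict=False)
    max_abs_diff = float(np.max(np.abs(dx.values - dz.values)))
    return dx, dz, max_abs_diff


@dataclass
class EvalReport:
    """Aggregate report: dist + per-classifier TSTR metrics (+ optional key
    gene correlation comparison)."""

    dist: float
    classification: dict[str, dict] = field(default_factory=dict)
    key_genes: dict | None = None

    def to_dict(self) -> dict:
        return {
            "dist": self.dist,
            "classification": self.classification,
            "key_genes": self.key_genes,
        }


def evaluate_generated(
    real_test: ExpressionDataset,
    generated: ExpressionDataset,
    classifiers: Sequence[str] = ("rf", "knn", "mlp"),
    repeats: int = 10,
    seed: int = 0,
    key_genes: Sequence[str] | None = None,
) -> EvalReport:
    """Full evaluation of a generated cohort against held-out real data."""
    dx = gene_pearson_matrix(real_test.values, real_test.gene_names,
                             strict=False)
    dz = gene_pearson_matrix(generated.values, generated.gene_names,
                             strict=False)
    report = EvalReport(dist=dist_score(dx, dz))
    for spec in classifiers:
        report.classification[spec] = tstr_classification_eval(
            generated, real_test, spec, repeats=repeats, seed=seed
        )
    if key_genes:
        kx, kz, max_diff = key_gene_correlation(real_test, generated, key_genes)
        report.key_genes = {
            "genes": list(key_genes),
            "real": kx.values.tolist(),
            "generated": kz.values.tolist(),
            "max_abs_difference": max_diff,
        }
    return report
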