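"""scikit-learn-style estimator for conditional expression augmentation.

``MDWGANGP`` wraps the whole pipeline — KNN-graph view enrichment, the
multi-critic conditional WGAN-GP, early stopping on the gene-correlation
``dist`` score — behind fit/sample/score.  It composes with sklearn model
selection (get_params/set_params) and accepts either a plain array plus a
two-column label array or an :class:`ExpressionDataset`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .dataset import ExpressionDataset
from .errors import ParameterError
from .evaluate import dist_score, gene_pearson_matrix
from .gan import GanConfig, sample_noise
from .graph import enrich_views
from .io import stratified_split
from .train import train_mdwgan

__all__ = ["MDWGANGP"]


def _as_dataset(X, y) -> ExpressionDataset:
    if isinstance(X, ExpressionDataset):
        return X
    X = np.asarray(X, dtype=float)
    labels = np.asarray(y, dtype=object)
    if labels.ndim == 1:  # condition only; single pseudo-tissue
        tissue = np.asarray(["all"] * X.shape[0], dtype=object)
        condition = labels
    elif labels.ndim == 2 and labels.shape[1] == 2:
        tissue, condition = labels[:, 0], labels[:, 1]
    else:
        raise ParameterError(
            "y must be a condition vector or an (n, 2) array of "
            "(tissue, condition) labels"
        )
    return ExpressionDataset(
        values=X,
        sample_ids=[f"X{i}" for i in range(X.shape[0])],
        gene_names=[f"G{j}" for j in range(X.shape[1])],
        tissue=tissue,
        condition=condition,
    )


class MDWGANGP(BaseEstimator):
    """Multi-critic conditional WGAN-GP data augmenter.

    Parameters mirror :class:`gexgan.gan.GanConfig`; ``validation_fraction``
    controls the internal stratified hold-out used for early stopping when
    no explicit validation set is passed to :meth:`fit`.

    Attributes (after fit)
    ----------------------
    model_ : the trained generator/critic pair with its label codec
    history_ : per-epoch losses and validation dist scores
    config_ : the resolved :class:`GanConfig`
    """

    def __init__(
        self,
        noise_dim: int = 128,
        hidden_sizes: tuple[int, ...] = (256, 256),
        lambda_gp: float = 10.0,
        lambda_g: float = 0.2,
        lambda_d: float = 0.02,
        learning_rate: float = 5e-4,
        n_critic: int = 5,
        batch_size: int = 32,
        max_epochs: int = 500,
        patience: int = 20,
        knn_k: int = 5,
        views_enabled: tuple[str, ...] = ("euclidean", "cosine"),
        validation_fraction: float = 0.2,
        seed: int = 0,
    ):
        self.noise_dim = noise_dim
        self.hidden_sizes = hidden_sizes
        self.lambda_gp = lambda_gp
        self.lambda_g = lambda_g
        self.lambda_d = lambda_d
        self.learning_rate = learning_rate
        self.n_critic = n_critic
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.knn_k = knn_k
        self.views_enabled = views_enabled
        self.validation_fraction = validation_fraction
        self.seed = seed

    # ------------------------------------------------------------------
    def _config(self) -> GanConfig:
        return GanConfig(
            noise_dim=self.noise_dim,
            hidden_sizes=tuple(self.hidden_sizes),
            lambda_gp=self.lambda_gp,
            lambda_g=self.lambda_g,
            lambda_d=self.lambda_d,
            learning_rate=self.learning_rate,
            n_critic=self.n_critic,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            knn_k=self.knn_k,
            views_enabled=tuple(self.views_enabled),
            seed=self.seed,
        )

    def fit(self, X, y=None, validation_data=None) -> "MDWGANGP":
        """Fit on normalized expression values with (tissue, condition)
        labels.

        ``validation_data`` may be an :class:`ExpressionDataset` or an
        ``(X_val, y_val)`` pair; when absent, ``validation_fraction`` of the
        training samples is held out per stratum.
        """
        dataset = _as_dataset(X, y)
        config = self._config()
        if validation_data is None:
            train, val = stratified_split(
                dataset, 1.0 - self.validation_fraction, seed=self.seed
            )
        else:
            train = dataset
            if isinstance(validation_data, ExpressionDataset):
                val = validation_data
            else:
                val = _as_dataset(*validation_data)
        views = enrich_views(train, k=config.knn_k)
        self.model_, self.history_ = train_mdwgan(views, val, config)
        self.config_ = config
        self.n_genes_ = dataset.n_genes
        return self

    # ------------------------------------------------------------------
    def sample(
        self,
        labels=None,
        n: int | None = None,
        tissue: str = "all",
        condition: str = "cancer",
        random_state: int | None = None,
    ) -> np.ndarray:
        """Generate expression rows for the requested class labels.

        Either pass ``labels`` (a sequence of (tissue, condition) pairs) or
        ``n`` with a single ``tissue``/``condition``.
        """
        self._check_fitted()
        if labels is None:
            if n is None:
                raise ParameterError("pass labels or n")
            labels = [(tissue, condition)] * n
        labels = [tuple(map(str, tc)) for tc in labels]
        seed = self.seed if random_state is None else random_state
        z = sample_noise(len(labels), self.config_.noise_dim, seed)
        return self.model_.generate(z, labels)

    def sample_dataset(
        self, labels, random_state: int | None = None, prefix: str = "GEN"
    ) -> ExpressionDataset:
        """Like :meth:`sample` but wrapped in an ExpressionDataset."""
        values = self.sample(labels=labels, random_state=random_state)
        labels = [tuple(map(str, tc)) for tc in labels]
        return ExpressionDataset(
            values=values,
            sample_ids=[f"{prefix}{i:05d}" for i in range(len(labels))],
            gene_names=self.model_.gene_names
            or [f"G{j}" for j in range(self.n_genes_)],
            tissue=np.asarray([t for t, _ in labels], dtype=object),
            condition=np.asarray([c for _, c in labels], dtype=object),
        )

    def score(self, X, y=None, random_state: int | None = None) -> float:
        """Gene-correlation ``dist`` between X and a generated batch of the
        same size and labels (higher is better; 1 is perfect)."""
        self._check_fitted()
        dataset = _as_dataset(X, y)
        fake = self.sample(
            labels=dataset.class_labels(), random_state=random_state
        )
        dx = gene_pearson_matrix(dataset.values, dataset.gene_names,
                                 strict=False)
        dz = gene_pearson_matrix(fake, dataset.gene_names, strict=False)
        return dist_score(dx, dz)

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise ParameterError("estimator is not fitted; call fit first")
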