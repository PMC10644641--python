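"""Conditional generator, weight-tied critics, and the adversarial losses.

One generator G maps [noise, one-hot(tissue, condition)] to a synthetic
expression vector.  Three critics D1, D2, D3 score the raw and the two
graph-smoothed training views; they are fully weight-tied (a single
parameter collection evaluated on all three views), so the multi-view
structure enters only through the per-view loss terms and their weights.

Per view i the critic objective is the conditional WGAN-GP value

    V_i = E[D(X_i|Y)] - E[D(G(Z|Y)|Y)]
          + lambda_gp * E[(||grad_xhat D(xhat_i|Y)||_2 - 1)^2],

with xhat_i a per-sample uniform interpolation between X_i and the fake
batch.  The aggregate generator loss weights the auxiliary views by
lambda_g/2 and the aggregate critic loss weights them by lambda_d/2; the
penalty enters the minimized critic loss with a positive sign (standard
WGAN-GP practice) and the generator loss carries no penalty term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import AlignmentError, CodecError, ParameterError
from .nn import MLP

__all__ = [
    "GanConfig",
    "LabelCodec",
    "GanModel",
    "sample_noise",
    "generate_samples",
    "critic_value",
    "gradient_penalty",
    "per_view_objective",
    "generator_loss",
    "discriminator_loss",
    "save_checkpoint",
    "load_checkpoint",
]

VIEW_METRICS = {2: "euclidean", 3: "cosine"}
CHECKPOINT_VERSION = 1


@dataclass
class GanConfig:
    """Hyperparameters of the multi-critic conditional WGAN-GP.

    Defaults follow the published training recipe: two 256-unit ReLU
    hidden layers in both networks, RMSProp at learning rate 5e-4, gradient
    penalty weight lambda_gp = 10, auxiliary-view weights lambda_g = 0.2
    (generator) and lambda_d = 0.02 (critic), at most 500 epochs with
    early-stopping patience 20.
    """

    noise_dim: int = 128
    hidden_sizes: tuple[int, ...] = (256, 256)
    lambda_gp: float = 10.0
    lambda_g: float = 0.2
    lambda_d: float = 0.02
    learning_rate: float = 5e-4
    n_critic: int = 5
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 20
    knn_k: int = 5
    views_enabled: tuple[str, ...] = ("euclidean", "cosine")
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        self.views_enabled = tuple(self.views_enabled)
        if self.noise_dim < 1 or any(h < 1 for h in self.hidden_sizes):
            raise ParameterError("network sizes must be positive")
        if min(self.lambda_gp, self.lambda_g, self.lambda_d) < 0:
            raise ParameterError("loss weights must be non-negative")
        if self.learning_rate <= 0:
            raise ParameterError("learning rate must be positive")
        if min(self.n_critic, self.batch_size, self.max_epochs, self.knn_k) < 1:
            raise ParameterError("counts must be positive integers")
        if self.patience < 0:
            raise ParameterError("patience must be non-negative")
        unknown = set(self.views_enabled) - {"euclidean", "cosine"}
        if unknown:
            raise ParameterError(f"unknown auxiliary view(s): {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        d["views_enabled"] = list(self.views_enabled)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GanConfig":
        return cls(**d)

    def enabled_view_indices(self) -> list[int]:
        """Auxiliary view indices (2 and/or 3) currently enabled."""
        return [i for i, m in VIEW_METRICS.items() if m in self.views_enabled]


class LabelCodec:
    """Bijection between (tissue, condition) pairs and indicator vectors."""

    def __init__(self, classes: Sequence[tuple[str, str]]):
        self.classes = sorted({(str(t), str(c)) for t, c in classes})
        if not self.classes:
            raise ParameterError("codec needs at least one class")
        self._index = {tc: i for i, tc in enumerate(self.classes)}

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def encode(self, labels: Sequence[tuple[str, str]]) -> np.ndarray:
        out = np.zeros((len(labels), self.n_classes))
        for row, (t, c) in enumerate(labels):
            key = (str(t), str(c))
            if key not in self._index:
                raise CodecError(f"unknown (tissue, condition) pair {key}")
            out[row, self._index[key]] = 1.0
        return out

    def decode(self, onehot: np.ndarray) -> list[tuple[str, str]]:
        return [self.classes[int(i)] for i in np.argmax(onehot, axis=1)]


@dataclass
class GanModel:
    """Generator + single shared critic + label codec."""

    generator: MLP
    critic: MLP
    codec: LabelCodec
    n_genes: int
    noise_dim: int
    gene_names: list[str] = field(default_factory=list)

    @classmethod
    def initialize(
        cls,
        n_genes: int,
        codec: LabelCodec,
        config: GanConfig,
        rng: np.random.Generator,
        gene_names: list[str] | None = None,
    ) -> "GanModel":
        hidden = list(config.hidden_sizes)
        gen = MLP([config.noise_dim + codec.n_classes, *hidden, n_genes], rng)
        critic = MLP([n_genes + codec.n_classes, *hidden, 1], rng)
        return cls(
            generator=gen,
            critic=critic,
            codec=codec,
            n_genes=n_genes,
            noise_dim=config.noise_dim,
            gene_names=list(gene_names or []),
        )

    # convenience forward passes -------------------------------------
    def generate(
        self, z: np.ndarray, labels: Sequence[tuple[str, str]]
    ) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if z.shape[0] != len(labels):
            raise AlignmentError("noise rows and labels must align")
        y = self.codec.encode(labels)
        return self.generator(np.hstack([z, y]))

    def criticize(
        self, x: np.ndarray, labels: Sequence[tuple[str, str]]
    ) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.n_genes:
            raise AlignmentError(
                f"expected {self.n_genes} genes, got {x.shape[1]}"
            )
        if x.shape[0] != len(labels):
            raise AlignmentError("rows and labels must align")
        y = self.codec.encode(labels)
        return self.critic(np.hstack([x, y]))[:, 0]


# ---------------------------------------------------------------------
def sample_noise(n: int, noise_dim: int, seed: int | np.random.Generator) -> np.ndarray:
    """n x noise_dim standard-normal draws, deterministic given the seed."""
    if n < 1 or noise_dim < 1:
        raise ParameterError("n and noise_dim must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.standard_normal((n, noise_dim))


def generate_samples(
    model: GanModel, z: np.ndarray, labels: Sequence[tuple[str, str]]
) -> np.ndarray:
    return model.generate(z, labels)


def critic_value(
    model: GanModel, x: np.ndarray, labels: Sequence[tuple[str, str]]
) -> np.ndarray:
    return model.criticize(x, labels)


def interpolate(
    x_real: np.ndarray, x_fake: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample uniform interpolation eps*x_real + (1-eps)*x_fake."""
    x_real = np.asarray(x_real, dtype=float)
    x_fake = np.asarray(x_fake, dtype=float)
    if x_real.shape != x_fake.shape:
        raise AlignmentError("real and fake batches must share a shape")
    eps = rng.uniform(size=(x_real.shape[0], 1))
    return eps * x_real + (1.0 - eps) * x_fake


def gradient_penalty(
    model: GanModel,
    x_real: np.ndarray,
    x_fake: np.ndarray,
    labels: Sequence[tuple[str, str]],
    lambda_gp: float,
    seed: int | np.random.Generator,
) -> float:
    """lambda_gp * mean over samples of (||grad_xhat D(xhat|y)||_2 - 1)^2.

    The norm is taken over the expression coordinates of the critic input;
    the conditional label block is held fixed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xhat = interpolate(x_real, x_fake, rng)
    y = model.codec.encode(labels)
    if xhat.shape[0] != y.shape[0]:
        raise AlignmentError("batch and labels must align")
    g = model.critic.input_gradient(np.hstack([xhat, y]))[:, : model.n_genes]
    norms = np.linalg.norm(g, axis=1)
    return float(lambda_gp) * float(np.mean((norms - 1.0) ** 2))


def per_view_objective(
    model: GanModel,
    view_index: int,
    x_i: np.ndarray,
    x_fake: np.ndarray,
    labels: Sequence[tuple[str, str]],
    config: GanConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """(critic_term, penalty_term) of view ``view_index``'s objective.

    critic_term = mean D(X_i|Y) - mean D(fake|Y); penalty_term is the
    gradient penalty interpolating toward X_i.
    """
    if view_index not in (1, 2, 3):
        raise ParameterError("view_index must be 1, 2 or 3")
    if view_index in VIEW_METRICS and VIEW_METRICS[view_index] not in config.views_enabled:
        raise ParameterError(
            f"view {view_index} ({VIEW_METRICS[view_index]}) is disabled"
        )
    critic_term = float(
        np.mean(model.criticize(x_i, labels))
        - np.mean(model.criticize(x_fake, labels))
    )
    penalty_term = gradient_penalty(
        model, x_i, x_fake, labels, config.lambda_gp, seed
    )
    return critic_term, penalty_term


def generator_loss(g1: float, g2: float, g3: float, lambda_g: float) -> float:
    """Aggregate generator loss g1 + (lambda_g/2)*(g2 + g3), where g_i is
    the generator-dependent part -mean D(G(Z|Y)|Y) under view i."""
    return float(g1 + 0.5 * lambda_g * (g2 + g3))


def discriminator_loss(
    view_objectives: Sequence[tuple[float, float]], lambda_d: float
) -> float:
    """Minimized critic loss: -[c1 + (lambda_d/2)(c2+c3)]
    + [p1 + (lambda_d/2)(p2+p3)]."""
    (c1, p1), (c2, p2), (c3, p3) = view_objectives
    return float(
        -(c1 + 0.5 * lambda_d * (c2 + c3)) + (p1 + 0.5 * lambda_d * (p2 + p3))
    )


# ---------------------------------------------------------------------
def save_checkpoint(path: str, model: GanModel, config: GanConfig, stats=None) -> None:
    """Single .npz archive with parameters + JSON metadata (versioned)."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": config.to_dict(),
        "classes": model.codec.classes,
        "n_genes": model.n_genes,
        "noise_dim": model.noise_dim,
        "gene_names": model.gene_names,
        "generator_sizes": model.generator.sizes,
        "critic_sizes": model.critic.sizes,
        "normalization": None
        if stats is None
        else {
            "gene_names": stats.gene_names,
            "per_gene_mean": stats.per_gene_mean.tolist(),
            "per_gene_std": stats.per_gene_std.tolist(),
            "log_base": stats.log_base,
            "pseudocount": stats.pseudocount,
        },
    }
    arrays = {"meta": np.array(json.dumps(meta))}
    for i, p in enumerate(model.generator.parameters()):
        arrays[f"gen_{i}"] = p
    for i, p in enumerate(model.critic.parameters()):
        arrays[f"critic_{i}"] = p
    np.savez(path, **arrays)


def load_checkpoint(path: str):
    """Returns (model, config, stats-or-None)."""
    from .preprocess import NormalizationStats

    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ParameterError(
                f"unsupported checkpoint version {meta['version']}"
            )
        config = GanConfig.from_dict(meta["config"])
        codec = LabelCodec([tuple(tc) for tc in meta["classes"]])
        gen = MLP(meta["generator_sizes"], np.random.default_rng(0))
        critic = MLP(meta["critic_sizes"], np.random.default_rng(0))
        gen.set_parameters(
            [archive[f"gen_{i}"] for i in range(2 * gen.n_layers)]
        )
        critic.set_parameters(
            [archive[f"critic_{i}"] for i in range(2 * critic.n_layers)]
        )
    model = GanModel(
        generator=gen,
        critic=critic,
        codec=codec,
        n_genes=int(meta["n_genes"]),
        noise_dim=int(meta["noise_dim"]),
        gene_names=list(meta["gene_names"]),
    )
    stats = None
    if meta["normalization"] is not None:
        stats = NormalizationStats(**meta["normalization"])
    return model, config, stats
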