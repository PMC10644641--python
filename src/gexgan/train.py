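"""Adversarial training loop: RMSProp, per-iteration validation, early
stopping.

One training iteration is the canonical WGAN-GP cycle: ``n_critic`` critic
minibatch updates followed by one generator update.  Minibatches are drawn
from a without-replacement cycle over the training split (reshuffled
whenever exhausted, last short batch kept).  After each iteration the model
generates a freshly-seeded batch matching the validation labels and the
gene-gene correlation similarity ``dist`` between the validation set and
that batch is recorded; training stops when the score has not strictly
improved for ``patience`` consecutive iterations, or at ``max_epochs``
iterations.  The returned model carries the parameters of the best-scoring
iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import ExpressionDataset
from .errors import (
    AlignmentError,
    DegenerateDataError,
    DivergenceError,
    ParameterError,
)
from .evaluate import dist_score, gene_pearson_matrix
from .gan import GanConfig, GanModel, LabelCodec, interpolate
from .graph import EnrichedViews
from .nn import RMSProp, add_scaled

__all__ = [
    "EarlyStopping",
    "TrainingHistory",
    "train_mdwgan",
    "run_ablation",
    "validation_dist",
]

ABLATION_VARIANTS = {
    "full": ("euclidean", "cosine"),
    "euclidean_only": ("euclidean",),
    "cosine_only": ("cosine",),
    "none": (),
}


class EarlyStopping:
    """Consecutive-non-improvement early stopping.

    An evaluation "improves" when its score strictly exceeds the previous
    evaluation's (no tolerance).  Training stops once ``max(patience, 1)``
    consecutive evaluations fail to improve (patience 0 therefore stops at
    the first non-improving evaluation).  Independently of the stopping
    counter, the best score and its index are tracked for checkpointing.
    """

    def __init__(self, patience: int):
        if patience < 0:
            raise ParameterError("patience must be non-negative")
        self.patience = patience
        self.best_score = -np.inf
        self.best_index: int | None = None
        self.prev_score = -np.inf
        self.n_bad = 0
        self._count = 0

    def update(self, score: float) -> bool:
        """Record one evaluation; returns True if it set a new best."""
        self._count += 1
        if score > self.prev_score:
            self.n_bad = 0
        else:
            self.n_bad += 1
        self.prev_score = score
        if score > self.best_score:
            self.best_score = score
            self.best_index = self._count
            return True
        return False

    @property
    def should_stop(self) -> bool:
        return self.n_bad >= max(self.patience, 1)


class _BatchCycler:
    """Without-replacement minibatch stream, reshuffled when exhausted."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        self.n = n
        self.batch_size = batch_size
        self.rng = rng
        self._order = rng.permutation(n)
        self._pos = 0

    def next_batch(self) -> np.ndarray:
        if self._pos >= self.n:
            self._order = self.rng.permutation(self.n)
            self._pos = 0
        idx = self._order[self._pos : self._pos + self.batch_size]
        self._pos += self.batch_size
        return idx


@dataclass
class TrainingHistory:
    """Per-iteration training records (iteration numbering is 1-based)."""

    generator_loss: list[float] = field(default_factory=list)
    discriminator_loss: list[float] = field(default_factory=list)
    critic_terms: list[tuple[float, float, float]] = field(default_factory=list)
    penalty_terms: list[tuple[float, float, float]] = field(default_factory=list)
    validation_score: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stop_reason: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.validation_score)


def validation_dist(
    model: GanModel,
    validation: ExpressionDataset,
    z: np.ndarray,
) -> float:
    """dist between the validation set's gene Pearson matrix and that of a
    generated batch with matching labels; -1.0 when the generated batch is
    correlation-degenerate (e.g. a collapsed generator)."""
    fake = model.generate(z, validation.class_labels())
    try:
        dx = gene_pearson_matrix(validation.values, validation.gene_names,
                                 strict=False)
        dz = gene_pearson_matrix(fake, validation.gene_names, strict=False)
        return dist_score(dx, dz)
    except DegenerateDataError:
        return -1.0


def _view_weights(config: GanConfig, lam: float) -> dict[int, float]:
    """Loss weight per view index: 1 for the raw view, lam/2 per enabled
    auxiliary view.  Zero-weight views are omitted outright so that
    lam = 0 reduces exactly (random stream included) to the plain
    single-critic conditional WGAN-GP."""
    weights = {1: 1.0}
    if lam > 0:
        for i in config.enabled_view_indices():
            weights[i] = 0.5 * lam
    return weights


def train_mdwgan(
    views: EnrichedViews,
    validation: ExpressionDataset,
    config: GanConfig,
) -> tuple[GanModel, TrainingHistory]:
    """Train the multi-critic conditional WGAN-GP on enriched views.

    ``views`` must come from the (normalized) training split; ``validation``
    is a disjoint dataset on the same genes used only for the per-epoch
    dist score driving early stopping and best-model selection.
    """
    n_genes = views.x1.shape[1]
    if validation.n_genes != n_genes:
        raise AlignmentError("views and validation differ in gene count")
    labels = list(zip(views.tissue.tolist(), views.condition.tolist()))
    codec = LabelCodec(labels)
    # independent, reproducible random streams
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_shuffle, rng_noise, rng_gp, rng_val = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    model = GanModel.initialize(
        n_genes, codec, config, rng_init, gene_names=validation.gene_names
    )
    opt_critic = RMSProp(model.critic.parameters(), config.learning_rate)
    opt_gen = RMSProp(model.generator.parameters(), config.learning_rate)

    y_all = codec.encode(labels)
    n = views.n_samples
    d_weights = _view_weights(config, config.lambda_d)
    g_weight = sum(_view_weights(config, config.lambda_g).values())

    history = TrainingHistory()
    stopper = EarlyStopping(config.patience)
    best_params: tuple[list, list] | None = None
    stop_reason = "max_epochs"
    batches = _BatchCycler(n, config.batch_size, rng_shuffle)

    for iteration in range(1, config.max_epochs + 1):
        iter_d_losses: list[float] = []
        iter_c_terms = np.zeros(3)
        iter_p_terms = np.zeros(3)
        for _ in range(config.n_critic):
            idx = batches.next_batch()
            bsz = len(idx)
            y = y_all[idx]
            batch_labels = [labels[i] for i in idx]
            # ---------------- critic update ----------------
            z = rng_noise.standard_normal((bsz, config.noise_dim))
            fake = model.generate(z, batch_labels)
            grads = None
            # generated samples enter every enabled view's critic term
            out_f, cache_f = model.critic.forward(
                np.hstack([fake, y]), with_cache=True
            )
            total_w = sum(d_weights.values())
            g_f, _ = model.critic.backward(
                cache_f, np.full((bsz, 1), total_w / bsz)
            )
            grads = add_scaled(grads, g_f)
            c_terms = np.zeros(3)
            p_terms = np.zeros(3)
            for view, w in d_weights.items():
                x_i = views.view(view)[idx]
                out_r, cache_r = model.critic.forward(
                    np.hstack([x_i, y]), with_cache=True
                )
                g_r, _ = model.critic.backward(
                    cache_r, np.full((bsz, 1), -w / bsz)
                )
                grads = add_scaled(grads, g_r)
                xhat = interpolate(x_i, fake, rng_gp)
                p_val, g_p = model.critic.penalty_gradients(
                    np.hstack([xhat, y]), n_genes, config.lambda_gp
                )
                grads = add_scaled(grads, g_p, w)
                c_terms[view - 1] = float(np.mean(out_r) - np.mean(out_f))
                p_terms[view - 1] = p_val
            d_loss = float(
                sum(
                    w * (-c_terms[v - 1] + p_terms[v - 1])
                    for v, w in d_weights.items()
                )
            )
            if not np.isfinite(d_loss):
                raise DivergenceError(
                    f"non-finite critic loss at iteration {iteration}"
                )
            opt_critic.step(grads)
            iter_d_losses.append(d_loss)
            iter_c_terms += c_terms
            iter_p_terms += p_terms
        # ---------------- generator update ----------------
        z = rng_noise.standard_normal((bsz, config.noise_dim))
        gen_in = np.hstack([z, y])
        fake_g, cache_g = model.generator.forward(gen_in, with_cache=True)
        out_g, cache_c = model.critic.forward(
            np.hstack([fake_g, y]), with_cache=True
        )
        _, dx = model.critic.backward(
            cache_c, np.full((bsz, 1), -g_weight / bsz)
        )
        gen_grads, _ = model.generator.backward(cache_g, dx[:, :n_genes])
        gen_loss = float(-g_weight * np.mean(out_g))
        if not np.isfinite(gen_loss):
            raise DivergenceError(
                f"non-finite generator loss at iteration {iteration}"
            )
        opt_gen.step(gen_grads)

        # freshly generated validation batch, deterministically seeded
        z_val = rng_val.standard_normal(
            (validation.n_samples, config.noise_dim)
        )
        score = validation_dist(model, validation, z_val)
        history.generator_loss.append(gen_loss)
        history.discriminator_loss.append(float(np.mean(iter_d_losses)))
        history.critic_terms.append(tuple(iter_c_terms / config.n_critic))
        history.penalty_terms.append(tuple(iter_p_terms / config.n_critic))
        history.validation_score.append(score)
        if stopper.update(score):
            best_params = (
                model.generator.copy_parameters(),
                model.critic.copy_parameters(),
            )
        if stopper.should_stop:
            stop_reason = "patience"
            break

    history.stop_reason = stop_reason
    history.best_epoch = stopper.best_index or history.n_epochs
    if best_params is not None:
        model.generator.set_parameters(best_params[0])
        model.critic.set_parameters(best_params[1])
    return model, history


def run_ablation(
    views: EnrichedViews,
    validation: ExpressionDataset,
    config: GanConfig,
    variant: str,
) -> tuple[GanModel, TrainingHistory]:
    """Train one ablation variant: ``full`` (both auxiliary views),
    ``euclidean_only``, ``cosine_only``, or ``none`` (the plain
    single-critic conditional WGAN-GP reduction)."""
    if variant not in ABLATION_VARIANTS:
        raise ParameterError(
            f"variant must be one of {sorted(ABLATION_VARIANTS)}"
        )
    cfg = replace(config, views_enabled=ABLATION_VARIANTS[variant])
    return train_mdwgan(views, validation, cfg)
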