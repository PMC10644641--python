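import numpy as np
import pytest

from gexgan import (
    CohortSpec,
    ExpressionDataset,
    make_synthetic_cohort,
    make_toy_fixture,
)


@pytest.fixture
def toy():
    """6-sample x 4-gene, 2-class dataset with hand-checkable structure."""
    return make_toy_fixture()


@pytest.fixture
def raw_counts():
    """Small non-negative raw-scale dataset for normalization tests."""
    rng = np.random.default_rng(42)
    values = rng.gamma(shape=2.0, scale=30.0, size=(12, 5))
    return ExpressionDataset(
        values=values,
        sample_ids=[f"S{i}" for i in range(12)],
        gene_names=[f"G{j}" for j in range(5)],
        tissue=np.asarray(["Liver"] * 6 + ["Lung"] * 6, dtype=object),
        condition=np.asarray(["normal", "cancer"] * 6, dtype=object),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Two-class synthetic cohort used by several integration tests."""
    return make_synthetic_cohort(
        CohortSpec(
            n_genes=10,
            classes=(("Kidney", "normal", 30), ("Kidney", "cancer", 30)),
            block_sizes=(3, 3),
            within_block_correlation=0.7,
            effect_size=3.0,
            seed=7,
        )
    )


def tiny_gan_config(**overrides):
    """Fast GanConfig for loop-mechanics tests (not for quality checks)."""
    from gexgan import GanConfig

    defaults = dict(
        noise_dim=8,
        hidden_sizes=(16, 16),
        batch_size=16,
        max_epochs=5,
        patience=50,
        knn_k=3,
        seed=0,
    )
    defaults.update(overrides)
    return GanConfig(**defaults)
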