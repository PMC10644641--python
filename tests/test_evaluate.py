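"""Gene correlation matrices, the dist similarity, confusion metrics, TSTR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gexgan import (
    ConfusionCounts,
    ExpressionDataset,
    confusion_metrics,
    dist_score,
    gene_pearson_matrix,
    key_gene_correlation,
    tstr_classification_eval,
)
from gexgan.evaluate import GeneDistanceMatrix, confusion_from_predictions
from gexgan.errors import AlignmentError, DegenerateDataError, ParameterError


def brute_force_dist(dx: np.ndarray, dz: np.ndarray) -> float:
    """Direct summation over upper-triangle pairs with population moments."""
    n = dx.shape[0]
    ux = [dx[i, j] for i in range(n - 1) for j in range(i + 1, n)]
    uz = [dz[i, j] for i in range(n - 1) for j in range(i + 1, n)]
    ux, uz = np.asarray(ux), np.asarray(uz)
    mu_x, mu_z = ux.mean(), uz.mean()
    sd_x = np.sqrt(np.mean((ux - mu_x) ** 2))
    sd_z = np.sqrt(np.mean((uz - mu_z) ** 2))
    total = sum(
        (x - mu_x) / sd_x * (z - mu_z) / sd_z for x, z in zip(ux, uz)
    )
    return total / len(ux)


def random_corr(rng, n_genes=10, n_samples=40):
    x = rng.normal(size=(n_samples, n_genes))
    return gene_pearson_matrix(x)


class TestGenePearsonMatrix:
    def test_hand_worked_three_columns(self):
        x = np.array([[1.0, 2.0, 0.0], [2.0, 4.0, 1.0], [3.0, 6.0, 1.0]])
        d = gene_pearson_matrix(x, ["a", "b", "c"])
        assert d.values[0, 1] == pytest.approx(1.0)
        assert d.values[0, 2] == pytest.approx(np.sqrt(3) / 2, abs=1e-12)
        assert d.values[1, 2] == pytest.approx(np.sqrt(3) / 2, abs=1e-12)
        np.testing.assert_allclose(np.diag(d.values), 1.0)

    def test_duplicated_and_negated_columns(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=20)
        d = gene_pearson_matrix(np.column_stack([col, col, -col]))
        assert d.values[0, 1] == pytest.approx(1.0)
        assert d.values[0, 2] == pytest.approx(-1.0)

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(15, 20))
        d = gene_pearson_matrix(x)
        np.testing.assert_allclose(d.values, np.corrcoef(x.T), atol=1e-12)

    def test_zero_variance_strict_names_gene(self):
        x = np.ones((5, 2))
        x[:, 0] = np.arange(5.0)
        with pytest.raises(DegenerateDataError, match="GBAD"):
            gene_pearson_matrix(x, ["GOK", "GBAD"])

    def test_zero_variance_lenient_reports_zero(self):
        x = np.ones((5, 3))
        x[:, 0] = np.arange(5.0)
        x[:, 2] = np.arange(5.0) ** 2
        d = gene_pearson_matrix(x, strict=False)
        assert d.values[0, 1] == 0.0 and d.values[1, 2] == 0.0
        assert d.values[1, 1] == 1.0


class TestDistScore:
    def test_self_similarity_is_exactly_one(self):
        d = random_corr(np.random.default_rng(0))
        assert dist_score(d, d) == 1.0

    def test_negated_off_diagonals_score_minus_one(self):
        d = random_corr(np.random.default_rng(1))
        neg = -d.values
        np.fill_diagonal(neg, 1.0)
        dz = GeneDistanceMatrix(neg, d.gene_names)
        assert dist_score(d, dz) == pytest.approx(-1.0, abs=1e-12)

    def test_invariant_under_common_gene_permutation(self):
        rng = np.random.default_rng(2)
        dx, dz = random_corr(rng), random_corr(rng)
        dz = GeneDistanceMatrix(dz.values, dx.gene_names)
        base = dist_score(dx, dz)
        perm = rng.permutation(dx.n_genes)
        names = [dx.gene_names[i] for i in perm]
        dxp = GeneDistanceMatrix(dx.values[np.ix_(perm, perm)], names)
        dzp = GeneDistanceMatrix(dz.values[np.ix_(perm, perm)], names)
        assert dist_score(dxp, dzp) == pytest.approx(base, abs=1e-12)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            dx, dz = random_corr(rng), random_corr(rng)
            dz = GeneDistanceMatrix(dz.values, dx.gene_names)
            assert dist_score(dx, dz) == pytest.approx(
                brute_force_dist(dx.values, dz.values), abs=1e-12
            )

    def test_independent_structures_score_near_zero(self):
        rng = np.random.default_rng(4)
        dx = random_corr(rng, n_genes=50, n_samples=500)
        dz = GeneDistanceMatrix(
            random_corr(rng, n_genes=50, n_samples=500).values, dx.gene_names
        )
        assert abs(dist_score(dx, dz)) < 0.2

    def test_gene_mismatch_and_degeneracy_errors(self):
        rng = np.random.default_rng(5)
        dx = random_corr(rng)
        other = GeneDistanceMatrix(
            dx.values, [f"other{j}" for j in range(dx.n_genes)]
        )
        with pytest.raises(AlignmentError):
            dist_score(dx, other)
        flat = GeneDistanceMatrix(np.ones((4, 4)), list("abcd"))
        with pytest.raises(DegenerateDataError):
            dist_score(flat, flat)
        small = GeneDistanceMatrix(np.eye(2), list("ab"))
        with pytest.raises(ParameterError):
            dist_score(small, small)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall",
                                         "f1", "mcc"))

    def test_chance_level(self):
        m = confusion_metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert m["accuracy"] == 0.5
        assert m["mcc"] == pytest.approx(0.0)

    def test_worked_example(self):
        m = confusion_metrics(ConfusionCounts(tp=40, tn=30, fp=10, fn=20))
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["precision"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(2 / 3, abs=1e-4)
        assert m["f1"] == pytest.approx(0.72727, abs=1e-5)
        assert m["mcc"] == pytest.approx(1000 / np.sqrt(6_000_000), abs=1e-6)

    def test_undefined_metrics_reported_as_missing(self):
        m = confusion_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=5))
        assert m["precision"] is None
        assert m["recall"] == 0.0
        assert m["f1"] is None
        assert m["mcc"] is None

    def test_agrees_with_brute_force_recounting(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            truth = rng.integers(0, 2, size=n)
            pred = rng.integers(0, 2, size=n)
            labels = np.where(truth == 1, "cancer", "normal")
            calls = np.where(pred == 1, "cancer", "normal")
            c = confusion_from_predictions(labels, calls)
            assert c.tp == int(np.sum((truth == 1) & (pred == 1)))
            assert c.tn == int(np.sum((truth == 0) & (pred == 0)))
            assert c.fp == int(np.sum((truth == 0) & (pred == 1)))
            assert c.fn == int(np.sum((truth == 1) & (pred == 0)))
            m = confusion_metrics(c)
            assert m["accuracy"] == pytest.approx(np.mean(truth == pred))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_mcc_invariant_under_class_swap(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0:
            counts = (1, 1, 1, 1)
            tp, tn, fp, fn = counts
        m1 = confusion_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        m2 = confusion_metrics(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp))
        if m1["mcc"] is not None and m2["mcc"] is not None:
            assert m1["mcc"] == pytest.approx(m2["mcc"], abs=1e-12)
        assert m1["accuracy"] == pytest.approx(m2["accuracy"], abs=1e-12)


def two_class_dataset(rng, n_per_class=60, n_genes=5, separation=3.0,
                      prefix="s"):
    normal = rng.normal(size=(n_per_class, n_genes))
    cancer = rng.normal(size=(n_per_class, n_genes)) + separation
    values = np.vstack([normal, cancer])
    n = 2 * n_per_class
    return ExpressionDataset(
        values=values,
        sample_ids=[f"{prefix}{i}" for i in range(n)],
        gene_names=[f"G{j}" for j in range(n_genes)],
        tissue=np.asarray(["T"] * n, dtype=object),
        condition=np.asarray(
            ["normal"] * n_per_class + ["cancer"] * n_per_class, dtype=object
        ),
    )


class TestTstrClassification:
    def test_separated_classes_reach_high_accuracy(self):
        rng = np.random.default_rng(0)
        generated = two_class_dataset(rng, prefix="g")
        real = two_class_dataset(rng, prefix="r")
        res = tstr_classification_eval(generated, real, "rf", repeats=2,
                                       seed=0)
        assert res["mean"]["accuracy"] >= 0.95

    def test_label_permutation_null_has_near_zero_mcc(self):
        rng = np.random.default_rng(1)
        generated = two_class_dataset(rng, prefix="g")
        real = two_class_dataset(rng, prefix="r")
        generated.condition = rng.permutation(generated.condition)
        res = tstr_classification_eval(generated, real, "knn", repeats=1,
                                       seed=0)
        assert abs(res["mean"]["mcc"]) < 0.3

    def test_single_class_generated_set_is_degenerate(self):
        rng = np.random.default_rng(2)
        generated = two_class_dataset(rng)
        generated.condition[:] = "cancer"
        real = two_class_dataset(rng)
        with pytest.raises(DegenerateDataError):
            tstr_classification_eval(generated, real, "rf")

    @pytest.mark.parametrize("spec", ["knn", "mlp"])
    def test_other_classifier_specs_run(self, spec):
        rng = np.random.default_rng(3)
        generated = two_class_dataset(rng, n_per_class=25)
        real = two_class_dataset(rng, n_per_class=25)
        res = tstr_classification_eval(generated, real, spec, repeats=1,
                                       seed=0)
        assert 0.0 <= res["mean"]["accuracy"] <= 1.0

    def test_unknown_spec_rejected(self):
        rng = np.random.default_rng(4)
        ds = two_class_dataset(rng, n_per_class=10)
        with pytest.raises(ParameterError):
            tstr_classification_eval(ds, ds, "svm")


class TestKeyGeneCorrelation:
    def test_identical_datasets_have_zero_difference(self, small_cohort):
        genes = small_cohort.gene_names[:4]
        dx, dz, diff = key_gene_correlation(small_cohort, small_cohort, genes)
        np.testing.assert_allclose(dx.values, dz.values)
        assert diff == 0.0
        assert dx.gene_names == genes

    def test_two_gene_matrices_have_unit_diagonal(self, small_cohort):
        genes = small_cohort.gene_names[:2]
        dx, dz, _ = key_gene_correlation(small_cohort, small_cohort, genes)
        assert dx.values.shape == (2, 2)
        np.testing.assert_allclose(np.diag(dx.values), 1.0)

    def test_missing_gene_named_in_error(self, small_cohort):
        with pytest.raises(AlignmentError, match="MISSING"):
            key_gene_correlation(
                small_cohort, small_cohort, ["G000", "MISSING"]
            )

    def test_matches_direct_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        real = two_class_dataset(rng, prefix="r")
        gen = two_class_dataset(rng, prefix="g")
        genes = ["G1", "G3"]
        dx, dz, _ = key_gene_correlation(real, gen, genes)
        sub = real.values[:, [1, 3]]
        r = np.corrcoef(sub.T)[0, 1]
        assert dx.values[0, 1] == pytest.approx(r, abs=1e-12)
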