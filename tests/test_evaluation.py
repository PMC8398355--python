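"""Evaluation statistics, subject-wise splits, and report algebra."""

import numpy as np
import pytest
from dataclasses import replace

from semgfusion.evaluation import (
    EvalReport,
    SplitSpec,
    accuracy,
    confusion,
    correlation_matrix,
    five_number_summary,
    md,
    qd,
    split_by_subjects,
    stdev,
)
from semgfusion.synthetic import AcquisitionSpec, NoiseSpec, generate_dataset


@pytest.fixture(scope="module")
def tiny_dataset():
    acq = AcquisitionSpec(n_subjects=10, n_classes=2,
                          trials_per_class_per_subject=1, duration=0.1)
    return generate_dataset(acq, NoiseSpec(), seed=0)


class TestSplitBySubjects:
    def test_two_test_subjects(self, tiny_dataset):
        train, test = split_by_subjects(tiny_dataset, SplitSpec(frozenset({1, 2})))
        assert {t.subject_id for t in test} == {1, 2}
        assert len({t.subject_id for t in train}) == 8
        assert not ({t.subject_id for t in train} & {1, 2})

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(frozenset())

    def test_partition_is_complete(self, tiny_dataset):
        train, test = split_by_subjects(tiny_dataset, SplitSpec(frozenset({3})))
        assert len(train) + len(test) == len(tiny_dataset)

    def test_unknown_subject_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            split_by_subjects(tiny_dataset, SplitSpec(frozenset({99})))

    def test_all_subjects_in_test_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            split_by_subjects(tiny_dataset, SplitSpec(frozenset(range(1, 11))))


class TestAccuracy:
    def test_all_correct(self):
        assert accuracy(np.array([1, 2, 3]), np.array([1, 2, 3])) == 100.0

    def test_two_thirds(self):
        assert accuracy(np.array([1, 2, 3]), np.array([1, 2, 4])) == pytest.approx(
            66.6667, abs=0.01
        )

    def test_random_guessing_near_chance(self):
        """12-class random predictions land within 3 s.e. of 8.33%."""
        rng = np.random.default_rng(0)
        n = 12000
        preds = rng.integers(1, 13, n)
        labels = rng.integers(1, 13, n)
        p = 1 / 12
        se = 100 * np.sqrt(p * (1 - p) / n)
        assert abs(accuracy(preds, labels) - 100 * p) < 3 * se

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.array([]), np.array([]))


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        labels = np.repeat(np.arange(1, 13), 3)
        mat = confusion(labels, labels)
        assert np.all(mat == np.diag(np.full(12, 3)))

    def test_single_mistake_location(self):
        mat = confusion(np.array([6]), np.array([4]))
        assert mat[3, 5] == 1 and mat.sum() == 1

    def test_trace_equals_accuracy(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 13, 500)
        preds = rng.integers(1, 13, 500)
        mat = confusion(preds, labels)
        assert np.trace(mat) / mat.sum() == pytest.approx(
            accuracy(preds, labels) / 100
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([13]), np.array([1]))


class TestDispersionStatistics:
    def test_constant_vector_gives_zero(self):
        x = np.full(8, 3.3)
        assert qd(x) == 0.0 and md(x) == 0.0 and stdev(x) == 0.0

    def test_stdev_hand_computed(self):
        assert stdev(np.array([1.0, 2.0, 3.0])) == pytest.approx(1.0)

    def test_md_hand_computed(self):
        # deviations from mean 2.5 are 1.5, 0.5, 0.5, 1.5 -> mean 1
        assert md(np.array([1.0, 2.0, 3.0, 4.0])) == pytest.approx(1.0)

    def test_qd_linear_interpolation(self):
        # type-7 quartiles of 1..5: Q1 = 2, Q3 = 4
        assert qd(np.array([1.0, 2.0, 3.0, 4.0, 5.0])) == pytest.approx(2.0)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            qd(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            md(np.array([1.0]))
        with pytest.raises(ValueError):
            stdev(np.array([1.0]))


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self):
        x = np.random.default_rng(2).random((3, 50))
        rho = correlation_matrix(x)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_anticorrelation(self):
        x = np.random.default_rng(3).random(40)
        rho = correlation_matrix(np.vstack([x, -x]))
        assert rho[0, 1] == pytest.approx(-1.0)

    def test_dual_formula_oracle(self):
        """cov/(sx sy) agrees with the expanded E(XY)-E(X)E(Y) form."""
        rng = np.random.default_rng(4)
        x, y = rng.random(200), rng.random(200)
        rho = correlation_matrix(np.vstack([x, y]))[0, 1]
        num = np.mean(x * y) - x.mean() * y.mean()
        den = np.sqrt(np.mean(x**2) - x.mean() ** 2) * np.sqrt(
            np.mean(y**2) - y.mean() ** 2
        )
        assert abs(rho - num / den) < 1e-12

    def test_symmetry_and_range(self):
        x = np.random.default_rng(5).random((6, 30))
        rho = correlation_matrix(x)
        np.testing.assert_allclose(rho, rho.T)
        assert rho.min() >= -1.0 and rho.max() <= 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(np.vstack([np.ones(10), np.arange(10.0)]))


class TestFiveNumberSummary:
    def test_median_of_1_to_100(self):
        s = five_number_summary(np.arange(1.0, 101.0))
        assert s["median"] == pytest.approx(50.5)

    def test_symmetric_data(self):
        x = np.random.default_rng(6).normal(size=2000)
        s = five_number_summary(x)
        assert abs(s["median"] - x.mean()) < 0.1

    def test_far_outlier_flagged(self):
        x = np.concatenate([np.random.default_rng(7).normal(size=100), [50.0]])
        s = five_number_summary(x)
        assert 50.0 in s["outliers"]
        assert s["max"] < 50.0  # whisker excludes the outlier

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            five_number_summary(np.arange(4.0))


def test_report_mean_is_arithmetic_mean():
    report = EvalReport(
        split_accuracies=[60.0, 80.0],
        confusion_matrix=np.zeros((12, 12), dtype=int),
        class_stats={},
        correlation=np.eye(12),
        box_summaries=[],
    )
    assert report.mean_accuracy == 70.0
    assert report.to_dict()["mean_accuracy"] == 70.0


def test_run_experiment_deterministic_and_complete():
    """Same seed, same report; report carries one accuracy per split."""
    from semgfusion.experiment import ExperimentConfig, run_experiment
    from semgfusion.dbn import DBNConfig
    from semgfusion.mffn import MFFNConfig, shape_plan

    acq = AcquisitionSpec(n_subjects=3, n_classes=3,
                          trials_per_class_per_subject=2, duration=1.0)
    mffn = MFFNConfig(input_size=32, block_sizes=(1, 1), growth_rate=4,
                      stem_filters=8, seed=0)
    cfg = ExperimentConfig(
        acquisition=acq,
        f_step=16.0,
        image_size=32,
        mffn=mffn,
        dbn=DBNConfig(layer_sizes=(shape_plan(mffn).flatten_length, 16, 8),
                      n_classes=3, pretrain_epochs=2, finetune_epochs=10, seed=0),
        splits=(frozenset({1}), frozenset({2})),
        seed=7,
    )
    r1 = run_experiment(cfg)
    r2 = run_experiment(cfg)
    assert r1.split_accuracies == r2.split_accuracies
    assert len(r1.split_accuracies) == 2
    np.testing.assert_array_equal(r1.confusion_matrix, r2.confusion_matrix)
    np.testing.assert_array_equal(r1.correlation, r2.correlation)
    # confusion-derived accuracy equals the mean of the reported accuracies
    # only when split sizes match; here they do
    derived = 100 * np.trace(r1.confusion_matrix) / r1.confusion_matrix.sum()
    assert derived == pytest.approx(np.mean(r1.split_accuracies))
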