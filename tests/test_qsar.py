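"""Random-forest QSAR: partitioning, metrics, ROC, applicability domain."""

import itertools

import numpy as np
import pytest

from insectscreen import qsar, synthetic
from insectscreen.curation import Label
from insectscreen.qsar import ConfusionCounts, DescriptorMatrix, QsarError, SplitSpec

from conftest import make_records
from insectscreen.curation import LabeledCompound


def _labeled(n_active, n_inactive):
    records = make_records([5.0] * n_active + [3.0] * n_inactive)
    return [
        LabeledCompound(r, Label.ACTIVE if r.plc50 >= 4.5 else Label.INACTIVE)
        for r in records
    ]


def mcc_by_correlation(tp, tn, fp, fn):
    """Independent oracle: MCC is the Pearson correlation of the binary
    truth/prediction vectors."""
    import warnings

    truth = [1] * tp + [1] * fn + [0] * tn + [0] * fp
    pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(truth, pred)[0, 1]
    return r


class TestStratifiedSplit:
    def test_exact_fractions(self):
        train, test = qsar.stratified_split(_labeled(5, 5), SplitSpec(0.8, seed=1))
        by = lambda group, lab: sum(1 for lc in group if lc.label is lab)
        assert (by(train, Label.ACTIVE), by(train, Label.INACTIVE)) == (4, 4)
        assert (by(test, Label.ACTIVE), by(test, Label.INACTIVE)) == (1, 1)

    def test_round_half_even_per_class(self):
        # 91 actives / 75 inactives at 80/20: test sizes round(18.2)=18, round(15.0)=15
        train, test = qsar.stratified_split(_labeled(91, 75), SplitSpec(0.8, seed=0))
        n_a = sum(1 for lc in test if lc.label is Label.ACTIVE)
        assert (n_a, len(test) - n_a) == (18, 15)
        assert len(train) + len(test) == 166
        assert {lc.record.compound_id for lc in train}.isdisjoint(
            {lc.record.compound_id for lc in test}
        )

    def test_deterministic_under_seed(self):
        a = qsar.stratified_split(_labeled(20, 20), SplitSpec(0.8, seed=42))
        b = qsar.stratified_split(_labeled(20, 20), SplitSpec(0.8, seed=42))
        ids = lambda half: [lc.record.compound_id for lc in half]
        assert ids(a[0]) == ids(b[0]) and ids(a[1]) == ids(b[1])

    def test_single_class_and_empty_test_class_rejected(self):
        with pytest.raises(QsarError, match="both classes"):
            qsar.stratified_split(_labeled(5, 0), SplitSpec(0.8, seed=0))
        with pytest.raises(QsarError, match="empty"):
            qsar.stratified_split(_labeled(2, 2), SplitSpec(0.9, seed=0))


class TestMatthewsCC:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(tp=76, fn=24, tn=76, fp=24), 0.52),
            (ConfusionCounts(tp=76, fn=24, tn=71, fp=29), 0.47),
            (ConfusionCounts(tp=73, fn=27, tn=67, fp=33), 0.40),
        ],
    )
    def test_balanced_model_summaries(self, counts, expected):
        assert round(qsar.matthews_cc(counts), 2) == expected

    def test_perfect_forecast(self):
        assert qsar.matthews_cc(ConfusionCounts(tp=8, tn=8, fp=0, fn=0)) == 1.0

    def test_exhaustive_small_matrices_match_correlation_oracle(self):
        for tp, tn, fp, fn in itertools.product(range(5), repeat=4):
            if tp + tn + fp + fn == 0:
                continue
            counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
            ours = qsar.matthews_cc(counts)
            oracle = mcc_by_correlation(tp, tn, fp, fn)
            if np.isnan(oracle):  # undefined denominator: random-forecast value
                assert ours == 0.0
            else:
                assert ours == pytest.approx(oracle, abs=1e-12)

    def test_balanced_closed_form(self):
        # balanced classes with ppv = sensitivity: mcc = sens + spec - 1
        for counts in [
            ConfusionCounts(tp=76, fn=24, tn=76, fp=24),
            ConfusionCounts(tp=76, fn=24, tn=71, fp=29),
        ]:
            report = qsar.PerformanceReport.from_counts(counts, auc=0.5)
            assert report.mcc == pytest.approx(
                report.sensitivity + report.specificity - 1, abs=5e-3
            )


class TestRoc:
    def test_perfect_and_reversed_rankings(self):
        labels = [Label.ACTIVE] * 3 + [Label.INACTIVE] * 3
        _, auc = qsar.compute_roc([0.9, 0.8, 0.7, 0.3, 0.2, 0.1], labels)
        assert auc == 1.0
        _, auc = qsar.compute_roc([0.1, 0.2, 0.3, 0.7, 0.8, 0.9], labels)
        assert auc == 0.0

    def test_tied_pair_counts_half(self):
        labels = [Label.ACTIVE, Label.ACTIVE, Label.INACTIVE, Label.INACTIVE]
        _, auc = qsar.compute_roc([0.9, 0.6, 0.6, 0.2], labels)
        assert auc == pytest.approx(0.875)  # 3 concordant + 0.5 tie over 4 pairs

    def test_pair_counting_equals_trapezoidal_area(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(4, 60))
            labels = [Label.ACTIVE if v else Label.INACTIVE for v in rng.integers(0, 2, n)]
            if len(set(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            curve, auc = qsar.compute_roc(scores, labels)
            assert auc == pytest.approx(np.trapezoid(curve[:, 1], curve[:, 0]), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(QsarError, match="per class"):
            qsar.compute_roc([0.1, 0.9], [Label.ACTIVE, Label.ACTIVE])


class TestForest:
    def test_separable_data_fits_training_set_perfectly(self, strong_signal_library):
        labeled, matrix, _ = strong_signal_library
        labels = [lc.label for lc in labeled]
        model = qsar.train_forest(matrix, labels, seed=0)
        report = qsar.evaluate(model, matrix, labels)
        assert report.accuracy == 1.0

    def test_same_seed_gives_identical_probabilities(self, strong_signal_library):
        _, matrix, _ = strong_signal_library
        labels = [Label.ACTIVE if i % 2 else Label.INACTIVE for i in range(matrix.n_compounds)]
        p1 = qsar.train_forest(matrix, labels, seed=5).predict_proba_active(matrix)
        p2 = qsar.train_forest(matrix, labels, seed=5).predict_proba_active(matrix)
        np.testing.assert_array_equal(p1, p2)

    def test_preconditions(self, strong_signal_library):
        _, matrix, _ = strong_signal_library
        labels = [Label.ACTIVE] * matrix.n_compounds
        with pytest.raises(QsarError, match="n_trees"):
            qsar.train_forest(matrix, labels, n_trees=0)
        with pytest.raises(QsarError, match="align"):
            qsar.train_forest(matrix, labels[:-1])


class TestEvaluate:
    def _matrix(self, n):
        return DescriptorMatrix(
            compound_ids=tuple(f"c{i}" for i in range(n)),
            descriptor_names=("d1",),
            values=np.arange(n, dtype=float).reshape(-1, 1),
        )

    def test_perfect_probability_vector(self):
        labels = [Label.ACTIVE] * 3 + [Label.INACTIVE] * 3
        counts = qsar.counts_from_probabilities([1, 1, 1, 0, 0, 0], labels)
        _, auc = qsar.compute_roc([1, 1, 1, 0, 0, 0], labels)
        report = qsar.PerformanceReport.from_counts(counts, auc)
        assert (
            report.sensitivity,
            report.specificity,
            report.accuracy,
            report.mcc,
            report.auc,
        ) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_constant_predictor_is_uninformative(self):
        labels = [Label.ACTIVE] * 4 + [Label.INACTIVE] * 4
        probs = [0.5] * 8
        counts = qsar.counts_from_probabilities(probs, labels)
        _, auc = qsar.compute_roc(probs, labels)
        report = qsar.PerformanceReport.from_counts(counts, auc)
        assert report.mcc == 0.0
        assert not (report.sensitivity > 0.5 and report.specificity > 0.5)
        assert auc == 0.5

    def test_empty_test_set_rejected(self, strong_signal_library):
        labeled, matrix, _ = strong_signal_library
        model = qsar.train_forest(matrix, [lc.label for lc in labeled], seed=0)
        empty = DescriptorMatrix(
            compound_ids=(), descriptor_names=matrix.descriptor_names,
            values=np.empty((0, len(matrix.descriptor_names))),
        )
        with pytest.raises(QsarError, match="empty"):
            qsar.evaluate(model, empty, [])


class TestCrossValidate:
    def test_deterministic_and_accurate_on_separable_data(self, strong_signal_library):
        labeled, matrix, _ = strong_signal_library
        r1 = qsar.cross_validate(labeled, matrix, k=5, seed=2, n_trees=100)
        r2 = qsar.cross_validate(labeled, matrix, k=5, seed=2, n_trees=100)
        assert r1 == r2
        assert r1.accuracy > 0.9

    def test_fold_count_preconditions(self, strong_signal_library):
        labeled, matrix, _ = strong_signal_library
        with pytest.raises(QsarError, match="k >= 2"):
            qsar.cross_validate(labeled, matrix, k=1)
        with pytest.raises(QsarError, match="smallest class"):
            qsar.cross_validate(labeled, matrix, k=10_000)


class TestApplicabilityDomain:
    def test_identical_points_collapse_the_domain(self):
        matrix = DescriptorMatrix(
            compound_ids=("a", "b", "c"),
            descriptor_names=("x", "y"),
            values=np.ones((3, 2)),
        )
        domain = qsar.fit_apd(matrix)
        assert (domain.d_bar, domain.sigma, domain.apd_threshold) == (0.0, 0.0, 0.0)

    def test_two_points_single_distance(self):
        matrix = DescriptorMatrix(
            compound_ids=("a", "b"), descriptor_names=("x",),
            values=np.array([[0.0], [2.0]]),
        )
        domain = qsar.fit_apd(matrix, z=0.5)
        assert (domain.d_bar, domain.sigma) == (2.0, 0.0)
        assert domain.apd_threshold == 2.0

    def test_z_zero_gives_mean_distance(self):
        rng = np.random.default_rng(0)
        matrix = DescriptorMatrix(
            compound_ids=tuple(f"c{i}" for i in range(20)),
            descriptor_names=("x", "y", "z"),
            values=rng.normal(size=(20, 3)),
        )
        domain = qsar.fit_apd(matrix, z=0.0)
        assert domain.apd_threshold == domain.d_bar

    def test_membership_and_boundary(self):
        matrix = DescriptorMatrix(
            compound_ids=("a", "b"), descriptor_names=("x",),
            values=np.array([[0.0], [2.0]]),
        )
        domain = qsar.fit_apd(matrix, z=0.5)  # APD = 2.0
        assert qsar.is_in_domain(domain, [0.0])  # a training point itself
        assert qsar.is_in_domain(domain, [4.0])  # exactly at distance APD
        assert not qsar.is_in_domain(domain, [4.001])  # beyond every neighbour

    def test_dimension_mismatch_rejected(self):
        matrix = DescriptorMatrix(
            compound_ids=("a", "b"), descriptor_names=("x",),
            values=np.array([[0.0], [2.0]]),
        )
        domain = qsar.fit_apd(matrix)
        with pytest.raises(QsarError, match="descriptors"):
            qsar.is_in_domain(domain, [0.0, 1.0])

    def test_shrinking_z_never_adds_membership(self):
        rng = np.random.default_rng(4)
        matrix = DescriptorMatrix(
            compound_ids=tuple(f"c{i}" for i in range(15)),
            descriptor_names=("x", "y"),
            values=rng.normal(size=(15, 2)),
        )
        queries = rng.normal(scale=3.0, size=(40, 2))
        for z_small, z_big in [(0.0, 0.25), (0.25, 0.5), (0.5, 2.0)]:
            small = qsar.fit_apd(matrix, z=z_small)
            big = qsar.fit_apd(matrix, z=z_big)
            for q in queries:
                if qsar.is_in_domain(small, q):
                    assert qsar.is_in_domain(big, q)

    def test_needs_two_rows(self):
        matrix = DescriptorMatrix(
            compound_ids=("a",), descriptor_names=("x",), values=np.array([[1.0]])
        )
        with pytest.raises(QsarError, match="at least 2"):
            qsar.fit_apd(matrix)
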