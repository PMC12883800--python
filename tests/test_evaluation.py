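import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support

from oracles import classification_metrics_bruteforce
from reference_data import CHANGES_DETECTED, CHANGES_IDENTIFIED, CHANGES_MISSED

from fscchange.evaluation import (
    ConfusionMatrix,
    PointPattern,
    confusion,
    detection_rate,
    metrics,
    nearest_neighbor_index,
)
from fscchange.exceptions import DegenerateInputError, FormatError


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        cm = confusion(["a", "b", "a"], ["a", "b", "a"])
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_exact_counts(self):
        ref = ["x"] * 50 + ["y"] * 50
        pred = ["x"] * 40 + ["y"] * 10 + ["x"] * 5 + ["y"] * 45
        cm = confusion(ref, pred, class_order=("x", "y"))
        assert cm.counts.tolist() == [[40, 10], [5, 45]]

    def test_empty_input_rejected(self):
        with pytest.raises(FormatError):
            confusion([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(FormatError):
            confusion(["a"], ["a", "b"])


class TestMetrics:
    def test_toy_matrix_hand_values(self):
        cm = ConfusionMatrix(np.array([[40, 10], [5, 45]]), ("x", "y"))
        report = metrics(cm)
        assert report.OA == pytest.approx(0.85)
        assert report.kappa == pytest.approx(0.70)

    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(np.diag([10, 20, 30]), ("a", "b", "c"))
        report = metrics(cm)
        assert report.OA == 1.0 and report.kappa == 1.0 and report.F1 == 1.0

    def test_one_class_predictor_has_zero_kappa(self):
        cm = ConfusionMatrix(np.array([[50, 0], [50, 0]]), ("x", "y"))
        report = metrics(cm)
        assert report.kappa == pytest.approx(0.0)
        assert report.flags  # class y never predicted

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 30, size=(5, 5))
            counts[0, 0] += 1  # nonempty
            cm = ConfusionMatrix(counts, tuple("abcde"))
            ours = metrics(cm)
            expected = classification_metrics_bruteforce(counts)
            assert ours.OA == pytest.approx(expected["OA"], abs=1e-12)
            assert ours.precision == pytest.approx(expected["precision"], abs=1e-12)
            assert ours.recall == pytest.approx(expected["recall"], abs=1e-12)
            assert ours.F1 == pytest.approx(expected["F1"], abs=1e-12)
            assert ours.kappa == pytest.approx(expected["kappa"], abs=1e-12)

    def test_matches_sklearn_on_random_labelings(self, rng):
        classes = np.array(list("abcde"))
        for _ in range(10):
            ref = classes[rng.integers(0, 5, 300)]
            pred = classes[rng.integers(0, 5, 300)]
            report = metrics(confusion(ref, pred, class_order=tuple(classes)))
            p, r, f, _ = precision_recall_fscore_support(
                ref, pred, average="macro", zero_division=0
            )
            assert report.precision == pytest.approx(p, abs=1e-12)
            assert report.recall == pytest.approx(r, abs=1e-12)
            assert report.F1 == pytest.approx(f, abs=1e-12)
            assert report.kappa == pytest.approx(cohen_kappa_score(ref, pred), abs=1e-12)

    def test_kappa_one_iff_perfect(self, rng):
        counts = rng.integers(1, 20, size=(3, 3))
        cm = ConfusionMatrix(counts, ("a", "b", "c"))
        report = metrics(cm)
        if report.OA < 1.0:
            assert report.kappa < 1.0

    def test_independent_predictions_have_near_zero_kappa(self, rng):
        # predictions drawn independently of the reference → kappa ≈ 0
        kappas = []
        for _ in range(20):
            ref = np.array(["a", "b"])[rng.integers(0, 2, 2000)]
            pred = np.array(["a", "b"])[rng.integers(0, 2, 2000)]
            kappas.append(metrics(confusion(ref, pred)).kappa)
        assert abs(np.mean(kappas)) < 0.02


class TestDetectionRate:
    def test_survey_accounting(self):
        reference = {f"c{i}" for i in range(CHANGES_IDENTIFIED)}
        detected_set = {f"c{i}" for i in range(CHANGES_DETECTED)} | {"other1", "other2"}
        detected, missed, rate = detection_rate(reference, detected_set)
        assert detected == CHANGES_DETECTED
        assert missed == CHANGES_MISSED
        assert rate == pytest.approx(CHANGES_DETECTED / CHANGES_IDENTIFIED)

    def test_full_detection(self):
        d, m, r = detection_rate({"a", "b"}, {"a", "b", "c"})
        assert (d, m, r) == (2, 0, 1.0)

    def test_disjoint_sets(self):
        d, m, r = detection_rate({"a", "b"}, {"c"})
        assert (d, m, r) == (0, 2, 0.0)

    def test_conservation(self, rng):
        for _ in range(20):
            ref = {f"r{i}" for i in rng.integers(0, 100, size=30)}
            det = {f"r{i}" for i in rng.integers(0, 100, size=30)}
            if not ref:
                continue
            d, m, _ = detection_rate(ref, det)
            assert d + m == len(ref)

    def test_empty_reference_degenerate(self):
        with pytest.raises(DegenerateInputError):
            detection_rate(set(), {"a"})


class TestNearestNeighborIndex:
    def test_square_lattice_is_two(self):
        s = 10.0
        xs, ys = np.meshgrid(np.arange(10) * s, np.arange(10) * s)
        pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
        pattern = PointPattern(pts, area=100 * s * s)
        nni, z, p = nearest_neighbor_index(pattern)
        assert nni == pytest.approx(2.0, abs=1e-6)
        assert z > 0 and p < 1e-6

    def test_coincident_points_zero(self):
        pattern = PointPattern(np.zeros((5, 2)), area=100.0)
        nni, z, _ = nearest_neighbor_index(pattern)
        assert nni == 0.0
        assert z < 0

    def test_csr_close_to_one(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pts = rng.uniform(0, 1000, size=(500, 2))
            nni, _, _ = nearest_neighbor_index(PointPattern(pts, 1000.0 * 1000.0))
            ok += 0.9 <= nni <= 1.1
        assert ok >= 9

    def test_clustered_pattern_below_one(self, rng):
        centers = rng.uniform(0, 1000, size=(5, 2))
        pts = np.vstack([c + rng.normal(0, 5, size=(40, 2)) for c in centers])
        nni, z, p = nearest_neighbor_index(PointPattern(pts, 1000.0 * 1000.0))
        assert nni < 0.5
        assert p < 0.001

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            PointPattern(np.zeros((1, 2)), 10.0)
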