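import numpy as np
import pytest

from ivusffr.metrics import (
    bland_altman,
    diagnostic_performance,
    dice,
    hausdorff,
    jaccard,
    roc_auc,
)


class TestOverlap:
    def test_identical_and_disjoint(self):
        a = np.zeros((10, 10), bool)
        a[2:6, 2:6] = True
        b = np.zeros_like(a)
        b[6:10, 6:10] = True
        assert dice(a, a) == 1.0 and jaccard(a, a) == 1.0
        assert dice(a, b) == 0.0 and jaccard(a, b) == 0.0

    def test_half_of_union_overlapping_rectangles(self):
        # equal-area strips whose intersection is half their union:
        # |A| = |B| = 12, overlap 8, union 16 -> J = 1/2, D = 2/3
        a = np.zeros((8, 16), bool)
        b = np.zeros_like(a)
        a[:, :12] = True
        b[:, 4:] = True
        assert dice(a, b) == pytest.approx(2 / 3)
        assert jaccard(a, b) == pytest.approx(1 / 2)

    def test_jaccard_dice_relation_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.random((12, 12)) > 0.5
            b = rng.random((12, 12)) > 0.5
            d, j = dice(a, b), jaccard(a, b)
            assert j == pytest.approx(d / (2 - d), abs=1e-12)

    def test_empty_masks_warn(self):
        z = np.zeros((4, 4), bool)
        with pytest.warns(UserWarning):
            assert dice(z, z) == 1.0
        with pytest.warns(UserWarning):
            assert jaccard(z, z) == 1.0

    def test_hausdorff(self):
        sq = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        assert hausdorff(sq, sq) == 0.0
        assert hausdorff(sq, sq + [3.0, 0.0]) == pytest.approx(np.hypot(3, 0), rel=1e-12)
        with pytest.raises(ValueError):
            hausdorff(sq, np.empty((0, 2)))


class TestBlandAltman:
    def test_identity(self):
        x = np.array([0.7, 0.8, 0.9, 0.85])
        agr = bland_altman(x, x)
        assert agr.bias == 0.0 and agr.loa_low == 0.0 and agr.loa_high == 0.0
        assert agr.pearson_r == pytest.approx(1.0)

    def test_constant_offset(self):
        x = np.array([0.7, 0.8, 0.9])
        agr = bland_altman(x, x + 0.01)
        assert agr.bias == pytest.approx(0.01)
        assert agr.sd == pytest.approx(0.0, abs=1e-15)

    def test_constant_series_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            agr = bland_altman(np.ones(5), np.arange(5.0))
        assert np.isnan(agr.pearson_r)

    def test_against_direct_formula(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(40), rng.random(40)
        agr = bland_altman(x, y)
        d = y - x
        assert agr.bias == pytest.approx(d.mean(), abs=1e-12)
        assert agr.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)
        assert agr.pearson_r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)


class TestDiagnosticPerformance:
    def test_known_2x2_table(self):
        # TP=8, FN=2, FP=1, TN=9
        truth = np.array([1] * 10 + [0] * 10, bool)
        pred = np.array([1] * 8 + [0] * 2 + [1] * 1 + [0] * 9, bool)
        rep = diagnostic_performance(pred, truth)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (8, 2, 1, 9)
        assert rep.sensitivity == pytest.approx(80.0)
        assert rep.specificity == pytest.approx(90.0)
        assert rep.accuracy == pytest.approx(85.0)
        assert rep.ppv == pytest.approx(100 * 8 / 9, abs=0.05)
        assert rep.npv == pytest.approx(100 * 9 / 11, abs=0.05)
        assert rep.plr == pytest.approx(8.0)
        assert rep.nlr == pytest.approx(0.222, abs=5e-4)
        lo, hi = rep.sensitivity_ci
        assert lo < 80.0 < hi
        assert "Accuracy" in rep.to_markdown()

    def test_perfect_prediction(self):
        truth = np.array([1, 1, 0, 0, 1], bool)
        rep = diagnostic_performance(truth, truth)
        assert rep.accuracy == rep.sensitivity == rep.specificity == 100.0
        assert rep.nlr == 0.0

    def test_all_positive_predictions(self):
        truth = np.array([1, 0, 0, 1], bool)
        rep = diagnostic_performance(np.ones(4, bool), truth)
        assert rep.specificity == 0.0
        assert rep.ppv == pytest.approx(50.0)  # prevalence


class TestROC:
    def test_perfect_separation(self):
        truth = np.array([0, 0, 0, 1, 1, 1], bool)
        auc, (lo, hi) = roc_auc([0.1, 0.2, 0.3, 0.7, 0.8, 0.9], truth)
        assert auc == 1.0 and hi <= 1.0

    def test_uninformative_scores(self):
        truth = np.array([0, 1, 0, 1], bool)
        auc, _ = roc_auc(np.ones(4), truth)
        assert auc == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        scores = np.round(rng.random(14), 1)  # deliberate ties
        truth = rng.random(14) > 0.5
        auc, _ = roc_auc(scores, truth)
        pos, neg = scores[truth], scores[~truth]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        scores = rng.random(30)
        truth = rng.random(30) > 0.6
        a1, _ = roc_auc(scores, truth)
        a2, _ = roc_auc(np.exp(5 * scores), truth)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_lower_vffr_is_positive_class_convention(self):
        # score = -vFFR: smaller vFFR must score higher for the diseased class
        vffr = np.array([0.6, 0.7, 0.75, 0.85, 0.9, 0.95])
        truth = vffr <= 0.8
        auc, _ = roc_auc(-vffr, truth)
        assert auc == 1.0

    def test_bootstrap_ci(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.normal(1, 1, 20), rng.normal(0, 1, 20)])
        truth = np.array([1] * 20 + [0] * 20, bool)
        auc, (lo, hi) = roc_auc(scores, truth, ci_method="bootstrap", n_boot=200, seed=0)
        assert lo <= auc <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], np.array([1, 1], bool))
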