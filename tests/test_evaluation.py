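import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clavibmd import evaluation as ev


def frame(gt, pred, sex=None):
    data = {"bmd_true": gt, "bmd_pred": pred}
    if sex is not None:
        data["sex"] = sex
    return pd.DataFrame(data)


class TestMae:
    def test_zero_for_identical(self):
        assert ev.mae(frame([0.9, 1.0], [0.9, 1.0])) == 0.0

    def test_worked_example(self):
        assert ev.mae(frame([1.0, 0.8], [0.9, 1.0])) == pytest.approx(0.15)

    def test_permutation_invariant(self, rng):
        gt = rng.uniform(0.4, 1.4, 20)
        pred = gt + rng.normal(0, 0.1, 20)
        perm = rng.permutation(20)
        assert ev.mae(frame(gt, pred)) == pytest.approx(
            ev.mae(frame(gt[perm], pred[perm])))

    def test_bounded_by_max_difference(self, rng):
        gt = rng.uniform(0.4, 1.4, 15)
        pred = gt + rng.normal(0, 0.1, 15)
        assert 0 <= ev.mae(frame(gt, pred)) <= np.abs(pred - gt).max()


class TestPearson:
    def test_perfect_correlation(self):
        g = [0.5, 0.9, 1.3, 0.7]
        assert ev.pearson_r(frame(g, g)) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        g = np.array([0.5, 0.9, 1.3, 0.7])
        assert ev.pearson_r(frame(g, -g + 2.0)) == pytest.approx(-1.0)

    def test_matches_hand_formula_on_toy_set(self):
        gt = np.array([0.6, 0.8, 1.0, 1.2])
        pred = np.array([0.7, 0.75, 1.1, 1.15])
        num = np.mean((gt - gt.mean()) * (pred - pred.mean()))
        hand = num / (gt.std() * pred.std())
        assert ev.pearson_r(frame(gt, pred)) == pytest.approx(hand)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ev.pearson_r(frame([1.0, 1.0, 1.0], [0.9, 1.0, 1.1]))


class TestDiceEval:
    def test_perfect_prediction(self):
        m = np.zeros((6, 6)); m[2:4, 2:4] = 1
        assert ev.dice_eval(m.astype(float), m) == 1.0

    def test_disjoint(self):
        a = np.zeros((6, 6)); a[0, 0] = 1
        b = np.zeros((6, 6)); b[5, 5] = 1
        assert ev.dice_eval(a, b) == 0.0

    def test_half_cover_gives_two_thirds(self):
        pred = np.ones((4, 4))
        gt = np.zeros((4, 4)); gt[:2, :] = 1
        assert ev.dice_eval(pred, gt) == pytest.approx(2.0 / 3.0)

    def test_soft_map_binarized_at_half(self):
        gt = np.zeros((4, 4)); gt[1, 1] = 1
        pred = np.full((4, 4), 0.49); pred[1, 1] = 0.51
        assert ev.dice_eval(pred, gt) == 1.0

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.dice_eval(np.zeros((3, 3)), np.zeros((3, 3)))


class TestBlandAltman:
    def test_identical_predictions(self):
        st_ = ev.bland_altman(frame([0.8, 1.0], [0.8, 1.0]))
        assert st_.bias == 0.0 and st_.loa_low == 0.0 and st_.loa_high == 0.0

    def test_constant_offset(self):
        st_ = ev.bland_altman(frame([0.8, 1.0, 1.2], [0.85, 1.05, 1.25]))
        assert st_.bias == pytest.approx(0.05)
        assert st_.loa_low == pytest.approx(0.05)
        assert st_.loa_high == pytest.approx(0.05)

    def test_symmetric_differences(self):
        # differences {-0.1, +0.1}: sample SD = 0.1*sqrt(2)
        st_ = ev.bland_altman(frame([1.0, 1.0], [0.9, 1.1]))
        sd = 0.1 * np.sqrt(2)
        assert st_.bias == pytest.approx(0.0)
        assert st_.loa_low == pytest.approx(-1.96 * sd)
        assert st_.loa_high == pytest.approx(1.96 * sd)
        assert st_.loa_low <= st_.bias <= st_.loa_high


class TestLowess:
    def test_constant_error_gives_flat_curve(self):
        gt = np.linspace(0.5, 1.3, 30)
        out = ev.lowess_error_trend(frame(gt, gt + 0.07), frac=0.5)
        np.testing.assert_allclose(out[:, 1], 0.07, atol=1e-8)

    def test_monotone_error_gives_nondecreasing_curve(self):
        gt = np.linspace(0.5, 1.3, 40)
        pred = gt + 0.05 * (gt - 0.4)   # |error| strictly increasing in gt
        out = ev.lowess_error_trend(frame(gt, pred), frac=0.4)
        assert np.all(np.diff(out[:, 1]) >= -1e-9)

    def test_one_row_per_distinct_gt(self, rng):
        gt = np.round(rng.uniform(0.5, 1.3, 50), 2)
        pred = gt + rng.normal(0, 0.05, 50)
        out = ev.lowess_error_trend(frame(gt, pred))
        assert len(out) == len(np.unique(gt))
        assert np.all(np.diff(out[:, 0]) > 0)

    def test_bad_frac_rejected(self):
        gt = np.linspace(0.5, 1.3, 10)
        with pytest.raises(ValueError):
            ev.lowess_error_trend(frame(gt, gt), frac=1.5)


class TestTscore:
    def test_osteoporosis_boundary_bmd(self):
        # female references: T = -2.5 at 1.010 - 2.5*0.119 = 0.7125
        assert ev.tscore(0.7125, "female") == pytest.approx(-2.5)
        assert abs(ev.bmd_from_tscore(-2.5, "female") - 0.713) <= 5e-4

    def test_osteopenia_boundary_bmd(self):
        assert ev.bmd_from_tscore(-1.0, "female") == pytest.approx(0.891)
        assert ev.tscore(0.891, "female") == pytest.approx(-1.0)

    def test_yam_maps_to_zero(self):
        assert ev.tscore(1.010, "female") == pytest.approx(0.0)
        assert ev.bmd_from_tscore(0.0, "male") == pytest.approx(1.024)

    def test_round_trip_identity(self, rng):
        refs = ev.ReferenceValues()
        for t in rng.normal(0, 2, 10):
            for sex in ("male", "female"):
                assert ev.tscore(ev.bmd_from_tscore(t, sex, refs), sex,
                                 refs) == pytest.approx(t, abs=1e-12)

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError):
            ev.tscore(1.0, "other")


class TestWhoClassification:
    @pytest.mark.parametrize("t,expected", [
        (-2.5, ev.OSTEOPOROSIS), (-3.1, ev.OSTEOPOROSIS),
        (-1.0, ev.NORMAL), (0.4, ev.NORMAL),
        (-1.7, ev.OSTEOPENIA), (-2.49, ev.OSTEOPENIA), (-1.01, ev.OSTEOPENIA),
    ])
    def test_boundary_inclusive_rules(self, t, expected):
        assert ev.classify_who(t) == expected

    def test_constant_on_class_intervals(self):
        refs = ev.ReferenceValues()
        for t, cls in [(-3.0, ev.OSTEOPOROSIS), (-1.5, ev.OSTEOPENIA),
                       (0.5, ev.NORMAL)]:
            bmd = ev.bmd_from_tscore(t, "female", refs)
            assert ev.classify_who(ev.tscore(bmd, "female", refs)) == cls

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ev.classify_who(float("nan"))


class TestClassificationReport:
    def test_perfect_predictions_all_ones(self):
        labels = [ev.OSTEOPOROSIS] * 3 + [ev.OSTEOPENIA] * 4 + [ev.NORMAL] * 5
        rep = ev.classification_report(labels, labels)
        for cls in ev.WHO_CLASSES:
            for metric in ("sensitivity", "specificity", "precision", "f1"):
                assert rep.per_class[cls][metric] == 1.0
        assert all(v == 1.0 for v in rep.macro.values())

    def test_hand_built_confusion_matches_tally(self):
        gt = ([ev.OSTEOPOROSIS] * 10 + [ev.OSTEOPENIA] * 10 + [ev.NORMAL] * 10)
        pred = ([ev.OSTEOPOROSIS] * 7 + [ev.OSTEOPENIA] * 3
                + [ev.OSTEOPENIA] * 8 + [ev.NORMAL] * 2
                + [ev.NORMAL] * 9 + [ev.OSTEOPENIA] * 1)
        rep = ev.classification_report(gt, pred)
        np.testing.assert_array_equal(rep.confusion,
                                      [[7, 3, 0], [0, 8, 2], [0, 1, 9]])
        # one-vs-rest tally for osteoporosis: TP=7 FN=3 FP=0 TN=20
        assert rep.per_class[ev.OSTEOPOROSIS]["sensitivity"] == pytest.approx(0.7)
        assert rep.per_class[ev.OSTEOPOROSIS]["specificity"] == pytest.approx(1.0)
        assert rep.per_class[ev.OSTEOPOROSIS]["precision"] == pytest.approx(1.0)
        # osteopenia: TP=8 FN=2 FP=4 TN=16
        assert rep.per_class[ev.OSTEOPENIA]["precision"] == pytest.approx(8 / 12)
        assert rep.per_class[ev.OSTEOPENIA]["specificity"] == pytest.approx(16 / 20)

    def test_macro_is_unweighted_mean(self):
        vals = (0.540, 0.645, 0.755)
        assert ev.macro_average(vals) == pytest.approx(np.mean(vals))
        assert round(ev.macro_average(vals), 3) == 0.647

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            ev.classification_report([ev.NORMAL], ["severe"])


def wilcoxon_signflip_p(d):
    """Exhaustive sign-flip null distribution of the signed-rank statistic."""
    r = stats.rankdata(np.abs(d))
    total = r.sum()
    w_obs = r[np.asarray(d) > 0].sum()
    m_obs = min(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product([1, -1], repeat=len(d)):
        w = sum(ri for ri, s in zip(r, signs) if s > 0)
        if min(w, total - w) <= m_obs:
            count += 1
    return count / 2 ** len(d)


class TestCompareModels:
    def test_identical_errors_not_significant(self):
        e = np.linspace(0.01, 0.2, 12)
        res = ev.compare_models(e, e)
        assert not res.significant

    def test_large_systematic_shift_detected(self, rng):
        a = np.abs(stats.cauchy.rvs(size=50, random_state=7)) * 0.02
        b = a + 0.05
        res = ev.compare_models(a, b)
        assert res.significant and res.p_value < 0.05
        assert res.test_name == "wilcoxon_signed_rank"

    def test_normal_differences_use_paired_t(self, rng):
        a = rng.normal(0.10, 0.01, 40)
        b = a + rng.normal(0.0, 0.005, 40)
        res = ev.compare_models(a, b)
        assert res.test_name in ("paired_t", "wilcoxon_signed_rank")
        if res.normality_p >= 0.05:
            assert res.test_name == "paired_t"

    def test_wilcoxon_matches_exhaustive_signflip_oracle(self, rng):
        a = rng.normal(0.1, 0.03, 9)
        b = a + rng.normal(0.02, 0.02, 9)
        d = a - b
        p_oracle = wilcoxon_signflip_p(d)
        p_scipy = float(stats.wilcoxon(a, b, method="exact").pvalue)
        assert p_scipy == pytest.approx(p_oracle, abs=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            ev.compare_models([0.1] * 6, [0.1] * 7)
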