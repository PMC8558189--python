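"""Midpoint-threshold classifier, exhaustive leave-p-out CV, band-power test."""

from math import comb

import numpy as np
import pytest

from elbnd import EEGRecord, SubjectFeatures, band_power_test, evaluate_all_channels, fit_threshold, leave_p_out_cv, predict
from elbnd.synthetic import CohortSpec, generate_cohort
from reference import brute_force_lpo


class TestThreshold:
    def test_midpoint(self):
        m = fit_threshold(np.array([0.030, 0.030, 0.035, 0.035]),
                          np.array([False, False, True, True]))
        assert m.criterion == pytest.approx(0.0325)

    def test_degenerate_equal_means(self):
        m = fit_threshold(np.array([0.03, 0.03]), np.array([False, True]))
        assert m.criterion == pytest.approx(0.03)

    def test_matches_summation_oracle(self, rng):
        v = rng.random(20)
        lab = rng.random(20) < 0.4
        if lab.all() or not lab.any():
            lab[0] = True
            lab[1] = False
        m = fit_threshold(v, lab)
        pos = [x for x, l in zip(v, lab) if l]
        neg = [x for x, l in zip(v, lab) if not l]
        expect = 0.5 * (sum(pos) / len(pos) + sum(neg) / len(neg))
        assert m.criterion == pytest.approx(expect, rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_threshold(np.array([1.0, 2.0]), np.array([True, True]))

    def test_tie_is_negative(self):
        m = fit_threshold(np.array([0.0, 1.0]), np.array([False, True]))
        assert predict(m, m.criterion) is False
        assert predict(m, m.criterion + 1e-12) is True
        assert predict(m, m.criterion - 1e-12) is False

    def test_non_finite_value(self):
        m = fit_threshold(np.array([0.0, 1.0]), np.array([False, True]))
        with pytest.raises(ValueError):
            predict(m, float("nan"))


class TestLeavePOut:
    def test_fold_count_small(self, rng):
        v = rng.random(5)
        lab = np.array([False, False, False, True, True])
        rep = leave_p_out_cv(v, lab, p=3)
        assert rep.n_folds + rep.n_skipped == comb(5, 3) == 10

    def test_separated_cohort_perfect(self, rng):
        v = np.concatenate([rng.normal(0.03, 0.0001, 10),
                            rng.normal(0.05, 0.0001, 8)])
        lab = np.array([False] * 10 + [True] * 8)
        rep = leave_p_out_cv(v, lab, p=3)
        assert rep.sensitivity == 100.0
        assert rep.specificity == 100.0
        assert rep.accuracy == 100.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("p", [1, 2, 3])
    def test_matches_brute_force_oracle(self, seed, p):
        rng = np.random.default_rng(seed)
        v = rng.random(8)
        lab = np.array([False, False, False, False, True, True, True, False])
        rep = leave_p_out_cv(v, lab, p=p)
        tp, fn, tn, fp, folds, skipped = brute_force_lpo(v, lab, p)
        assert rep.n_folds == folds
        assert rep.n_skipped == skipped
        assert rep.sensitivity == pytest.approx(100 * tp / (tp + fn))
        assert rep.specificity == pytest.approx(100 * tn / (tn + fp))
        assert rep.accuracy == pytest.approx(100 * (tp + tn) / (tp + tn + fp + fn))

    def test_label_swap_symmetry(self, rng):
        v = rng.random(9)
        lab = rng.random(9) < 0.5
        lab[0], lab[1] = True, False
        a = leave_p_out_cv(v, lab, p=2)
        b = leave_p_out_cv(-v, ~lab, p=2)
        assert a.sensitivity == pytest.approx(b.specificity)
        assert a.specificity == pytest.approx(b.sensitivity)

    def test_skipped_folds_counted(self):
        # one positive among five: every fold holding it out trains one-class
        v = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        lab = np.array([False, False, False, False, True])
        rep = leave_p_out_cv(v, lab, p=3)
        assert rep.n_skipped == comb(4, 2)  # positive in held-out set
        assert rep.n_folds == comb(5, 3) - comb(4, 2)

    def test_p_too_large(self):
        with pytest.raises(ValueError):
            leave_p_out_cv(np.ones(4), np.array([True, False, True, False]), p=4)

    def test_monotone_in_effect_size(self):
        """Pooled accuracy grows with the planted group separation."""
        accs = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            acc = 0.0
            for seed in range(20):
                rng = np.random.default_rng(seed)
                v = np.concatenate([rng.normal(0.0, 1.0, 8),
                                    rng.normal(delta, 1.0, 8)])
                lab = np.array([False] * 8 + [True] * 8)
                acc += leave_p_out_cv(v, lab, p=3).accuracy
            accs.append(acc / 20)
        assert accs == sorted(accs)
        assert accs[-1] > accs[0] + 10


def make_features(values_by_channel, labels):
    n = len(labels)
    out = []
    for i in range(n):
        out.append(SubjectFeatures(
            subject_id=f"s{i}", label=labels[i], device="",
            per_channel={ch: float(v[i]) for ch, v in values_by_channel.items()},
        ))
    return out


class TestEvaluateAllChannels:
    def test_signal_channel_beats_noise_channel(self, rng):
        labels = ["control"] * 10 + ["AD"] * 8
        v_signal = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 8)])
        v_noise = rng.normal(0, 1, 18)
        feats = make_features({"A": v_signal, "B": v_noise}, labels)
        reports = {r.channel: r for r in evaluate_all_channels(feats, p=3,
                                                               contrast="normal_vs_AD")}
        assert reports["A"].accuracy > reports["B"].accuracy

    def test_duplicated_channel_identical(self, rng):
        labels = ["control"] * 6 + ["AD"] * 5
        v = rng.normal(0, 1, 11)
        feats = make_features({"A": v, "B": v.copy()}, labels)
        ra, rb = evaluate_all_channels(feats, p=3, contrast="normal_vs_AD")
        assert (ra.sensitivity, ra.specificity, ra.accuracy) == \
               (rb.sensitivity, rb.specificity, rb.accuracy)

    def test_mci_contrast_small_group(self, rng):
        """Runs at the clinical MCI group size (7 positives)."""
        labels = ["control"] * 12 + ["MCI"] * 7 + ["AD"] * 3
        v = np.concatenate([rng.normal(0, 1, 12), rng.normal(2, 1, 7),
                            rng.normal(2, 1, 3)])
        feats = make_features({"A": v}, labels)
        (rep,) = evaluate_all_channels(feats, p=3, contrast="normal_vs_MCI")
        assert rep.n_folds + rep.n_skipped == comb(19, 3)  # AD subjects excluded
        assert 0 <= rep.accuracy <= 100

    def test_unknown_contrast(self):
        with pytest.raises(ValueError):
            evaluate_all_channels([], contrast="bogus")


def _records_from_noise(rng, n_subj, n_ch=2, n_samp=2560, boost_delta=1.0):
    from scipy.signal import butter, lfilter

    out = []
    b, a = butter(2, [2.0 / 64.0, 4.0 / 64.0], btype="band")
    for i in range(n_subj):
        x = rng.standard_normal((n_samp, n_ch))
        if boost_delta != 1.0:
            x += (boost_delta - 1.0) * lfilter(b, a, x, axis=0)
        out.append(EEGRecord(f"s{i}", x, 128.0, [f"C{j}" for j in range(n_ch)]))
    return out


class TestBandPower:
    def test_identical_groups_no_rejections(self, rng):
        group = _records_from_noise(rng, 5)
        df = band_power_test(group, group)
        assert not df["reject"].any()
        # identical data: t = 0, p = 1 wherever variance is nonzero
        assert (df.loc[~df["degenerate"], "p_value"] > 0.99).all()

    def test_planted_delta_shift_detected(self, rng):
        a = _records_from_noise(rng, 12)
        b = _records_from_noise(rng, 12, boost_delta=3.0)
        df = band_power_test(a, b)
        delta = df[df["band"] == "delta"]
        assert delta["reject"].all()
        assert (delta["mean_b"] > delta["mean_a"]).all()

    def test_degenerate_flagged(self):
        zero = [EEGRecord(f"s{i}", np.zeros((512, 1)), 128.0, ["C0"])
                for i in range(3)]
        df = band_power_test(zero, zero)
        assert df["degenerate"].all()
        assert not df["reject"].any()

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            band_power_test([], [])


def test_end_to_end_cv_on_synthetic_cohort(small_features):
    """The default moderate-overlap cohort classifies well above chance."""
    reports = evaluate_all_channels(small_features, p=3,
                                    contrast="normal_vs_positives")
    for rep in reports:
        assert rep.n_folds + rep.n_skipped == comb(12, 3)
        assert rep.accuracy >= 75.0


def test_separable_cohort_perfect_cv():
    """With a widely separated planted effect the CV is perfect."""
    from elbnd import extract_features, preprocess_record

    spec = CohortSpec(n_negative=5, n_positive=5, n_channels=2,
                      duration_s=60.0, innovation_sd_positive=1.2,
                      between_subject_sd=0.05, seed=11)
    feats = [extract_features(preprocess_record(r))
             for r in generate_cohort(spec)]
    for rep in evaluate_all_channels(feats, p=3, contrast="normal_vs_positives"):
        assert rep.sensitivity == 100.0
        assert rep.specificity == 100.0
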