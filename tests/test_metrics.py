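import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import donorscreen as ds
from donorscreen.metrics import (
    metric_report, sensitivity_threshold,
)


def brute_force_auroc(scores, labels):
    """All-pairs counting oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuroc:
    def test_hand_example(self):
        # positives {0.9, 0.4}, negatives {0.5, 0.1}: 3 of 4 pairs won
        s = np.array([0.9, 0.4, 0.5, 0.1])
        y = np.array([1, 1, 0, 0])
        assert ds.auroc(s, y) == pytest.approx(0.75)

    def test_separated_and_ties(self):
        assert ds.auroc(np.array([1, 1, 0, 0]), np.array([1, 1, 0, 0])) == 1.0
        assert ds.auroc(np.full(6, 0.5), np.array([1, 0, 1, 0, 1, 0])) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            ds.auroc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(4, 200)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert ds.auroc(s, y) == pytest.approx(brute_force_auroc(s, y))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_invariant_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        y = np.r_[np.ones(5, int), np.zeros(45, int)]
        s = rng.random(n)
        assert ds.auroc(np.exp(3 * s), y) == pytest.approx(ds.auroc(s, y))


class TestScaledBrier:
    def test_perfect_and_reference(self):
        y = np.array([1, 0, 0, 1])
        assert ds.scaled_brier(y.astype(float), y) == 1.0
        assert ds.scaled_brier(np.full(4, 0.5), y) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        y = np.array([1, 0, 0, 0])
        s = np.array([0.8, 0.1, 0.2, 0.1])
        assert ds.scaled_brier(s, y) == pytest.approx(1 - 0.025 / 0.1875)

    def test_order_invariant(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        s = rng.random(30)
        perm = rng.permutation(30)
        assert ds.scaled_brier(s, y) == pytest.approx(
            ds.scaled_brier(s[perm], y[perm])
        )


class TestSensSpec:
    @pytest.mark.parametrize(
        "kw, sens, spec",
        [
            (dict(tp=67, fn=13, fp=42, tn=522), 0.838, 0.926),
            (dict(tp=67, fn=13, fp=37, tn=527), 0.838, 0.934),
        ],
    )
    def test_printed_confusion_matrices(self, kw, sens, spec):
        s, sp, cm = ds.sensitivity_specificity(**kw)
        assert round(s, 3) == sens
        assert round(sp, 3) == spec
        assert sum(cm.values()) == sum(kw.values())

    def test_cutoff_closed_at_threshold(self):
        s = np.array([0.5, 0.49, 0.51])
        y = np.array([1, 0, 1])
        sens, spec, cm = ds.sensitivity_specificity(s, y, 0.5)
        assert cm == {"tp": 2, "fp": 0, "fn": 0, "tn": 1}


class TestBootstrap:
    def test_constant_metric_degenerate_interval(self):
        y = np.array([1, 0] * 20)
        s = y.astype(float)
        med, lo, hi = ds.bootstrap_ci(ds.auroc, s, y, B=100, seed=0)
        assert med == lo == hi == 1.0

    def test_same_seed_identical(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s = rng.random(60)
        a = ds.bootstrap_ci(ds.auroc, s, y, B=200, seed=9)
        b = ds.bootstrap_ci(ds.auroc, s, y, B=200, seed=9)
        assert a == b

    def test_interval_orders_and_covers_point(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.ones(20, int), np.zeros(80, int)]
        s = rng.random(100) + 0.5 * y
        med, lo, hi = ds.bootstrap_ci(ds.auroc, s, y, B=500, seed=1)
        assert lo <= med <= hi

    def test_coverage_of_known_auroc(self):
        """Binormal generator with known AUROC: 95% CI covers truth at a
        rate consistent with nominal coverage (reduced replicates)."""
        from scipy.stats import norm

        mu = 1.0
        truth = norm.cdf(mu / np.sqrt(2))  # binormal AUROC
        rng = np.random.default_rng(4)
        cover = 0
        reps = 120
        for _ in range(reps):
            y = np.r_[np.ones(30, int), np.zeros(120, int)]
            s = np.r_[rng.normal(mu, 1, 30), rng.normal(0, 1, 120)]
            _, lo, hi = ds.bootstrap_ci(ds.auroc, s, y, B=300,
                                        seed=int(rng.integers(2**31)))
            cover += lo <= truth <= hi
        assert cover / reps >= 0.90


class TestPairedZ:
    def test_identical_models_p_one(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.random(50)
        z, p = ds.paired_bootstrap_z(ds.auroc, s, s, y, B=100, seed=0)
        assert z == 0.0 and p == 1.0

    def test_power_on_separated_vs_random(self):
        rng = np.random.default_rng(6)
        y = np.r_[np.ones(40, int), np.zeros(160, int)]
        s_good = y + 0.01 * rng.random(200)
        s_rand = rng.random(200)
        z, p = ds.paired_bootstrap_z(ds.auroc, s_good, s_rand, y, B=500,
                                     seed=1)
        assert z > 0 and p < 0.01

    def test_shared_resamples_cancel_common_noise(self):
        """Pairing: comparing a model to itself plus epsilon must give tiny
        variance, unlike independent resampling."""
        rng = np.random.default_rng(7)
        y = np.r_[np.ones(30, int), np.zeros(120, int)]
        s = rng.random(150) + y
        z, p = ds.paired_bootstrap_z(ds.auroc, s, s * 0.999 + 1e-5, y,
                                     B=300, seed=2)
        assert p > 0.5  # nearly identical models are not distinguished


class TestDeriveCutoff:
    def test_order_statistic_rule(self):
        scores = np.array([0.9, 0.8, 0.7, 0.75, 0.71, 0.72, 0.73, 0.74,
                           0.76, 0.2])
        labels = np.ones(10, int)
        t = sensitivity_threshold(scores, labels, 0.90)
        assert t == sorted(scores, reverse=True)[8]

    def test_target_zero_degenerate(self):
        assert sensitivity_threshold(np.array([0.4]), np.array([1]), 0.0) == 0.0

    def test_mean_of_fold_thresholds(self):
        rng = np.random.default_rng(8)
        y = np.r_[np.ones(30, int), np.zeros(90, int)]
        X = y + rng.normal(0, 0.4, 120)

        def scores_fn(tr, te):
            return X[te]  # fixed scorer: folds differ only by membership

        res = ds.derive_cutoff(scores_fn, y, target_sens=0.9, k=3, seed=0)
        assert res.cutoff == pytest.approx(np.mean(res.fold_thresholds))
        for t in res.fold_thresholds:
            assert 0 <= t <= y.max() + 2

    def test_heldout_sensitivity_meets_target_by_construction(self):
        rng = np.random.default_rng(9)
        y = np.r_[np.ones(40, int), np.zeros(200, int)]
        X = 2.0 * y + rng.normal(0, 1, 240)
        from sklearn.model_selection import StratifiedKFold

        folds = list(
            StratifiedKFold(3, shuffle=True, random_state=0).split(
                np.zeros_like(y), y
            )
        )

        def scores_fn(tr, te):
            return X[te]

        res = ds.derive_cutoff(scores_fn, y, 0.9, 3, seed=0)
        for (tr, te), t in zip(folds, res.fold_thresholds):
            sens, _, _ = ds.sensitivity_specificity(X[te], y[te], t)
            assert sens >= 0.9


class TestCalibration:
    def test_counts_conserve_and_empty_bins_kept(self):
        s = np.full(10, 0.35)
        y = np.r_[np.ones(3, int), np.zeros(7, int)]
        tab = ds.calibration_curve(s, y, bins=10)
        assert len(tab) == 10
        assert tab["n"].sum() == 10
        assert (tab["n"] > 0).sum() == 1

    def test_asymptotic_calibration(self):
        rng = np.random.default_rng(10)
        s = rng.random(50_000)
        y = (rng.random(50_000) < s).astype(int)
        tab = ds.calibration_curve(s, y, bins=10)
        gaps = (tab["mean_predicted"] - tab["observed_fraction"]).abs()
        assert gaps.max() < 0.02


def test_metric_report_structure():
    rng = np.random.default_rng(11)
    y = np.r_[np.ones(25, int), np.zeros(100, int)]
    s1 = y * 0.7 + 0.3 * rng.random(125)
    s2 = rng.random(125)
    rep = metric_report({"nn": s1, "lm": s2}, y,
                        {"nn": 0.5, "lm": 0.5}, B=100, seed=0)
    for m in ("nn", "lm"):
        e = rep["models"][m]
        assert e["auroc"]["lo"] <= e["auroc"]["median"] <= e["auroc"]["hi"]
        assert sum(e["confusion"].values()) == 125
    assert "nn_vs_lm" in rep["comparisons"]
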