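"""Classifier stack: selection, base learners, stacker, integrated model,
LOOCV honesty and targeted-specificity thresholding."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from fragscreen.classifier import (
    AssayConfigs,
    BaseLearnerConfig,
    FeatureSelectionConfig,
    IntegratedModelConfig,
    StackerConfig,
    ThresholdPolicy,
    choose_threshold,
    run_loocv,
    select_features,
    train_base_learner,
    train_full,
    train_integrated,
    train_stacker,
)
from fragscreen.evaluation import roc_auc


class TestSelectFeatures:
    def test_strong_feature_selected_noise_mostly_not(self):
        rng = np.random.default_rng(0)
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 50))
        X[:, 7] += 10 * y  # group means 0 vs 10, sd 1
        idx = select_features(X, y)
        assert 7 in idx
        assert len(idx) < 10

    def test_constant_feature_excluded_without_error(self):
        y = np.repeat([0, 1], 10)
        X = np.column_stack([np.full(20, 3.14), np.r_[np.zeros(10), np.ones(10)]])
        idx = select_features(X, y)
        assert 0 not in idx and 1 in idx

    def test_single_sample_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError):
            select_features(X, np.array([1, 0, 0, 0, 0]))

    def test_null_selection_rate_matches_alpha(self):
        """Welch selection at p<0.01 on pure noise keeps ~1% of features
        (type-I error calibration, 200 replicate simulations)."""
        rng = np.random.default_rng(1)
        hits, total = 0, 0
        for _ in range(200):
            X = rng.normal(size=(100, 1000))
            y = np.repeat([0, 1], 50)
            hits += len(select_features(X, y))
            total += 1000
        frac = hits / total
        # 99.9% binomial CI around alpha = 0.01 at 200,000 trials
        se = np.sqrt(0.01 * 0.99 / total)
        assert abs(frac - 0.01) < 3.3 * se


class TestBaseLearner:
    CFG = BaseLearnerConfig(n_configs=3, inner_folds=3, seed=5)

    def test_separable_feature_gives_perfect_oof_auc(self):
        y = np.repeat([0, 1], 15)
        X = (y * 2.0 - 1.0)[:, None]  # exactly separable two-point feature
        fit = train_base_learner(X, y, self.CFG)
        assert roc_auc(fit.oof_prob, y) == 1.0
        assert ((fit.oof_prob >= 0) & (fit.oof_prob <= 1)).all()

    def test_null_labels_give_chance_level_oof_auc(self):
        rng = np.random.default_rng(3)
        aucs = []
        for s in range(8):
            X = rng.normal(size=(40, 5))
            y = np.repeat([0, 1], 20)
            fit = train_base_learner(X, y, dataclasses.replace(self.CFG, seed=s))
            aucs.append(roc_auc(fit.oof_prob, y))
        assert 0.35 < np.mean(aucs) < 0.65

    def test_same_data_and_seed_reproduce_fit(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 8))
        y = np.repeat([0, 1], 15)
        a = train_base_learner(X, y, self.CFG)
        b = train_base_learner(X, y, self.CFG)
        np.testing.assert_array_equal(a.oof_prob, b.oof_prob)
        assert a.booster.save_raw() == b.booster.save_raw()


class TestStacker:
    CFG = StackerConfig(n_lambda=4, inner_folds=3, seed=2)

    def test_perfect_base_score_dominates(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 20)
        oof_cnv = 0.1 + 0.8 * y + 0.01 * rng.random(40)  # separates perfectly
        oof_fsc = rng.random(40)  # noise
        fit = train_stacker(oof_cnv, oof_fsc, y, self.CFG)
        assert roc_auc(fit.predict(oof_cnv, oof_fsc), y) == 1.0

    def test_identical_base_scores_preserve_auc(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 20)
        s = np.clip(0.3 * y + 0.4 * rng.random(40), 0, 1)
        fit = train_stacker(s, s, y, self.CFG)
        assert roc_auc(fit.predict(s, s), y) == pytest.approx(roc_auc(s, y))

    def test_small_class_warns_but_proceeds(self):
        y = np.array([0] * 12 + [1] * 5)
        s = np.random.default_rng(2).random(17)
        with pytest.warns(UserWarning, match="unstable"):
            fit = train_stacker(s, s, y, self.CFG)
        assert ((fit.predict(s, s) >= 0) & (fit.predict(s, s) <= 1)).all()


class TestIntegrated:
    CFG = IntegratedModelConfig(seed=0)

    def test_informative_psa_separates(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 25)
        psa = np.where(y == 1, 30.0, 2.0) * np.exp(0.01 * rng.normal(size=50))
        cnv = rng.random(50)
        fsc = rng.random(50)
        fit = train_integrated(cnv, fsc, psa, y, self.CFG)
        assert roc_auc(fit.predict(cnv, fsc, psa), y) == 1.0

    def test_missing_psa_rejected(self):
        y = np.repeat([0, 1], 10)
        s = np.random.default_rng(1).random(20)
        psa = np.full(20, 5.0)
        psa[3] = np.nan
        with pytest.raises(ValueError, match="PSA"):
            train_integrated(s, s, psa, y, self.CFG)

    def test_round_budget_respected(self):
        y = np.repeat([0, 1], 15)
        s = y.astype(float)
        psa = np.full(30, 5.0)
        fit = train_integrated(s, s, psa, y, self.CFG)
        assert fit.best_iteration < 1000

    def test_informative_vs_uninformative_psa(self):
        """Adding an informative PSA never hurts, and usually helps, the
        integrated AUC (paired over seeds)."""
        wins = 0
        n_rep = 10
        for s in range(n_rep):
            rng = np.random.default_rng(100 + s)
            y = np.repeat([0, 1], 30)
            base = np.clip(0.5 + 0.25 * (2 * y - 1) + 0.3 * rng.normal(size=60), 0, 1)
            psa_flat = np.exp(rng.normal(1.2, 0.4, size=60))
            psa_info = np.exp(rng.normal(1.2 + 1.5 * y, 0.4))
            cfg = IntegratedModelConfig(seed=s)
            auc_flat = roc_auc(
                train_integrated(base, base, psa_flat, y, cfg).predict(base, base, psa_flat), y
            )
            auc_info = roc_auc(
                train_integrated(base, base, psa_info, y, cfg).predict(base, base, psa_info), y
            )
            wins += auc_info >= auc_flat
        assert wins >= int(0.9 * n_rep)


class TestLoocv:
    def _toy_data(self, n=12, p_cnv=6, p_fsc=4, signal=2.5, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        cnv = rng.normal(size=(n, p_cnv)) + signal * y[:, None] * (np.arange(p_cnv) < 2)
        fsc = rng.normal(size=(n, p_fsc)) + signal * y[:, None] * (np.arange(p_fsc) < 2)
        psa = np.exp(rng.normal(1.5 + 0.5 * y, 0.5))
        return cnv, fsc, psa, y

    CFG = AssayConfigs(
        base=BaseLearnerConfig(n_configs=2, inner_folds=2, rounds_range=(50, 120)),
        stacker=StackerConfig(n_lambda=3, inner_folds=2),
        seed=1,
    )

    def test_fold_count_and_score_ranges(self):
        cnv, fsc, psa, y = self._toy_data()
        scores = run_loocv(cnv, fsc, psa, y, self.CFG)
        assert len(scores) == 12
        for col in ("cnv_score", "fsc_score", "fragmentomic_score", "integrated_score"):
            assert scores[col].between(0, 1).all()
        assert (scores["provenance"] == "loocv").all()

    def test_heldout_sample_never_taints_its_own_fold(self):
        """Fold i's models are a function of the other n-1 samples only:
        retraining on those samples reproduces sample i's out-of-sample
        scores exactly, even after sample i's features are replaced by
        arbitrary junk."""
        i = 4
        cnv, fsc, psa, y = self._toy_data(seed=3)
        a = run_loocv(cnv, fsc, psa, y, self.CFG)
        mask = np.arange(12) != i
        fit = train_full(cnv[mask], fsc[mask], psa[mask], y[mask],
                         self.CFG.reseeded(i + 1))
        expected = fit.score(cnv[i], fsc[i], np.array([psa[i]]))
        for col in ("cnv_score", "fsc_score", "fragmentomic_score", "integrated_score"):
            assert a.loc[i, col] == pytest.approx(expected.loc[0, col], abs=1e-7)
        # junk features for the held-out sample: fold-i fit is untouched,
        # so the junk flows only through prediction with the same models
        junk_cnv, junk_fsc = np.full_like(cnv[i], 99.0), np.full_like(fsc[i], -99.0)
        cnv2, fsc2 = cnv.copy(), fsc.copy()
        cnv2[i], fsc2[i] = junk_cnv, junk_fsc
        b = run_loocv(cnv2, fsc2, psa, y, self.CFG)
        expected_junk = fit.score(junk_cnv, junk_fsc, np.array([psa[i]]))
        for col in ("cnv_score", "fsc_score", "fragmentomic_score", "integrated_score"):
            assert b.loc[i, col] == pytest.approx(expected_junk.loc[0, col], abs=1e-7)

    def test_tiny_or_single_class_cohorts_rejected(self):
        cnv, fsc, psa, y = self._toy_data()
        with pytest.raises(ValueError):
            run_loocv(cnv[:8], fsc[:8], psa[:8], y[:8], self.CFG)
        with pytest.raises(ValueError):
            run_loocv(cnv, fsc, psa, np.r_[np.ones(11, int), 0], self.CFG)


def brute_force_threshold(sub_scores, target):
    """Enumerate every candidate cut-point; smallest achieving the target."""
    s = np.unique(sub_scores)
    candidates = sorted(np.r_[(s[:-1] + s[1:]) / 2.0, np.inf])
    feasible = [t for t in candidates if np.mean(sub_scores < t) >= target]
    return min(feasible)


class TestChooseThreshold:
    def test_nine_samples_force_full_specificity(self):
        scores = np.arange(0.1, 1.0, 0.1)
        labels = np.zeros(9, int)
        psa = np.full(9, 6.0)
        res = choose_threshold(scores, labels, psa)
        assert res.threshold > scores.max()
        assert res.achieved_specificity == 1.0

    def test_hundred_sample_grid_lands_between_order_statistics(self):
        scores = np.linspace(0.005, 1.0, 100)
        res = choose_threshold(scores, np.zeros(100, int), np.full(100, 5.0))
        assert scores[97] < res.threshold <= scores[98]
        assert res.achieved_specificity >= 0.98
        assert res.threshold == brute_force_threshold(scores, 0.98)

    def test_separated_groups_pick_smallest_gap_candidate(self):
        rng = np.random.default_rng(0)
        neg = rng.uniform(0.0, 0.4, 120)
        pos = rng.uniform(0.6, 1.0, 40)
        scores = np.r_[neg, pos]
        labels = np.r_[np.zeros(120, int), np.ones(40, int)]
        psa = np.full(160, 5.0)
        res = choose_threshold(scores, labels, psa)
        # smallest candidate inside the subcohort that reaches the target
        assert res.threshold == brute_force_threshold(neg, 0.98)
        assert res.threshold < pos.min()

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        scores = np.round(rng.random(n), 2)  # ties likely
        labels = np.zeros(n, int)
        psa = rng.uniform(3.0, 12.0, n)
        sub = scores[psa >= 4.0]
        if len(sub) == 0:
            with pytest.raises(ValueError):
                choose_threshold(scores, labels, psa)
            return
        res = choose_threshold(scores, labels, psa)
        assert res.threshold == brute_force_threshold(sub, 0.98)
        assert res.achieved_specificity >= 0.98 or res.threshold == np.inf

    def test_monotone_tradeoff_in_threshold(self):
        from fragscreen.evaluation import confusion_metrics

        rng = np.random.default_rng(1)
        scores = rng.random(200)
        y = (rng.random(200) < 0.4).astype(int)
        prev_sens, prev_spec = 1.0, 0.0
        for t in np.linspace(0, 1.001, 25):
            m = confusion_metrics(scores, y, t)
            assert m.sensitivity <= prev_sens + 1e-12
            assert m.specificity >= prev_spec - 1e-12
            prev_sens, prev_spec = m.sensitivity, m.specificity

    def test_empty_subcohort_rejected(self):
        with pytest.raises(ValueError):
            choose_threshold(np.array([0.5]), np.array([0]), np.array([2.0]))


class TestTrainFull:
    def test_in_sample_scores_and_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        n = 30
        y = np.repeat([0, 1], 15)
        cnv = rng.normal(size=(n, 10)) + 2.0 * y[:, None] * (np.arange(10) < 3)
        fsc = rng.normal(size=(n, 8)) + 2.0 * y[:, None] * (np.arange(8) < 3)
        psa = np.exp(rng.normal(1.5, 0.5, n))
        cfg = AssayConfigs(base=BaseLearnerConfig(n_configs=2, inner_folds=3), seed=9)
        fit = train_full(cnv, fsc, psa, y, cfg)
        scores = fit.score(cnv, fsc, psa, provenance="in-sample")
        assert roc_auc(scores["fragmentomic_score"], y) > 0.9
        fit.save(tmp_path / "bundle")
        from fragscreen.classifier import FittedAssay

        back = FittedAssay.load(tmp_path / "bundle")
        scores2 = back.score(cnv, fsc, psa)
        for col in ("cnv_score", "fsc_score", "fragmentomic_score", "integrated_score"):
            np.testing.assert_allclose(scores[col], scores2[col], atol=1e-6)
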