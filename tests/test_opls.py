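import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabatch import (ci_from_se, crossvalidate_jackknife, fit_opls,
                       fit_oplsda, run_order_effect)
from metabatch.opls import jackknife_se, predict_scores, stratified_folds


class TestFitOplsda:
    def test_perfectly_predictive_limit(self, rng):
        y = np.array(["a"] * 10 + ["b"] * 10)
        dummy = (y == "b").astype(float)
        X = np.tile(dummy[:, None], (1, 6)) + rng.normal(0, 1e-4, size=(20, 6))
        m = fit_oplsda(X, y, n_orth=0)
        assert np.all(m.pcorr > 0.999)
        assert m.r2y_cum > 0.99

    def test_independent_column_has_small_pcorr(self):
        vals = []
        for s in range(200):
            rng = np.random.default_rng(s)
            y = np.array(["a"] * 20 + ["b"] * 20)
            X = rng.standard_normal((40, 8))
            X[:, :7] += (y == "b")[:, None] * rng.normal(1.0, 0.3, size=7)
            m = fit_oplsda(X, y, n_orth=1)
            vals.append(abs(m.pcorr.iloc[7]))  # column 7 independent of y
        assert np.mean(vals) < 0.2

    def test_pcorr_invariant_to_column_rescaling(self, two_class_data):
        X, y = two_class_data
        m1 = fit_oplsda(X, y, n_orth=1)
        X2 = X.copy()
        X2.iloc[:, 3] *= 10.0
        m2 = fit_oplsda(X2, y, n_orth=1)
        np.testing.assert_allclose(m1.pcorr, m2.pcorr, atol=1e-10)

    def test_pcorr_matches_bruteforce_pearson(self, two_class_data):
        X, y = two_class_data
        m = fit_oplsda(X, y, n_orth=1)
        Xs = (X - X.mean()) / X.std(ddof=1)
        for k, col in enumerate(X.columns):
            r = stats.pearsonr(m.t.to_numpy(), Xs[col].to_numpy())[0]
            assert abs(m.pcorr.iloc[k] - r) < 1e-10

    def test_pcorr_bounded(self, two_class_data):
        X, y = two_class_data
        m = fit_oplsda(X, y, n_orth=1)
        assert (m.pcorr.abs() <= 1 + 1e-12).all()

    def test_predictive_orthogonal_to_orthogonal_scores(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = np.array(["a"] * 12 + ["b"] * 12)
            X = r.standard_normal((24, 9))
            m = fit_oplsda(X, y, n_orth=2)
            t = m.t.to_numpy()
            for a in range(m.n_orth):
                to = m.t_orth.iloc[:, a].to_numpy()
                assert abs(t @ to) < 1e-6 * np.linalg.norm(t) * np.linalg.norm(to)

    def test_zero_orth_matches_pls_oracle(self, two_class_data):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = two_class_data
        m = fit_oplsda(X, y, n_orth=0)
        Xs = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        yd = (y == "case").astype(float).to_numpy()
        yc = (yd - yd.mean()) / yd.std(ddof=1)
        pls = sklearn.PLSRegression(n_components=1, scale=False).fit(Xs, yc)
        t_ref = pls.x_scores_[:, 0]
        sign = np.sign(t_ref @ m.t.to_numpy())
        np.testing.assert_allclose(m.t.to_numpy(), sign * t_ref, atol=1e-8)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError, match="2 classes"):
            fit_oplsda(X, ["a"] * 10)

    def test_positive_class_controls_sign(self, two_class_data):
        X, y = two_class_data
        m_case = fit_oplsda(X, y, n_orth=1, positive_class="case")
        m_ctrl = fit_oplsda(X, y, n_orth=1, positive_class="control")
        np.testing.assert_allclose(m_case.pcorr, -m_ctrl.pcorr, atol=1e-10)
        assert m_case.pcorr.iloc[0] > 0  # column 0 elevated in cases

    def test_r2x_partition(self, two_class_data):
        X, y = two_class_data
        m = fit_oplsda(X, y, n_orth=1)
        assert 0 < m.r2x_pred < 1
        assert 0 <= m.r2x_total <= 1 + 1e-12
        assert m.component_label == "1 + 1 + 0"


class TestCrossvalidateJackknife:
    def test_duplicated_data_gives_zero_se(self, rng):
        X = rng.standard_normal((10, 6))
        y = np.array(["a"] * 5 + ["b"] * 5)
        X7 = pd.DataFrame(np.vstack([X] * 7))
        y7 = np.tile(y, 7)
        fold = pd.Series(np.repeat(np.arange(7), 10))
        cv = crossvalidate_jackknife(X7, y7, fold_labels=fold)
        assert cv.n_groups == 7
        np.testing.assert_allclose(cv.jackknife_se, 0, atol=1e-12)

    def test_jackknife_formula_hand_values(self):
        # (0.5, 0.6, 0.7), N=3 -> sqrt((2/3) * 0.02)
        assert abs(jackknife_se([0.5, 0.6, 0.7]) - 0.11547005) < 1e-7

    def test_pure_noise_q2_nonpositive_majority(self):
        neg = 0
        n_rep = 100
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            X = rng.standard_normal((35, 20))
            y = np.array(["a"] * 18 + ["b"] * 17)
            neg += crossvalidate_jackknife(X, y, folds=7).q2 <= 0
        assert neg > n_rep / 2

    def test_strong_signal_q2_positive(self, two_class_data):
        X, y = two_class_data
        cv = crossvalidate_jackknife(X, y, folds=7)
        assert cv.q2 > 0.2
        assert cv.submodel_pcorr.shape == (7, X.shape[1])
        assert (cv.jackknife_se >= 0).all()

    def test_stratified_folds_keep_both_classes(self):
        y = pd.Series(["a"] * 6 + ["b"] * 6)
        fold = stratified_folds(y, 7)
        # 6 members per class into 7 folds: one fold empties and is dropped
        assert fold.max() == 5
        for g in range(int(fold.max()) + 1):
            assert y[fold != g].nunique() == 2

    def test_single_class_fold_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((8, 4)))
        y = np.array(["a"] * 4 + ["b"] * 4)
        bad = pd.Series([0] * 4 + [1] * 4)  # fold 0 training split is all 'b'
        with pytest.raises(ValueError, match="one class"):
            crossvalidate_jackknife(X, y, fold_labels=bad)

    def test_planted_effects_are_jackknife_significant(self):
        # at the synthetic study's planted effect size (1.5 sd) a single
        # batch of n = 35 should flag the effect metabolites significant
        # (|pcorr| > t * SE) in the large majority of replicates
        from metabatch import fit_batch
        from metabatch.synthetic_data import default_effects
        magnitude = abs(default_effects(12)).max()
        hits, total = 0, 0
        for s in range(50):
            rng = np.random.default_rng(300 + s)
            y = np.array(["a"] * 18 + ["b"] * 17)
            X = rng.standard_normal((35, 12))
            X[:, :3] += (y == "b")[:, None] * magnitude
            res = fit_batch(pd.DataFrame(X), y, folds=7, n_orth=1)
            hits += int(res.significant.iloc[:3].sum())
            total += 3
        assert hits / total >= 0.80


class TestCiFromSe:
    def test_zero_se_zero_ci(self):
        assert ci_from_se(0.0, 7) == 0.0

    def test_t_quantile_6df(self):
        assert abs(ci_from_se(1.0, 7) - 2.4469) < 1e-4

    def test_monotonic_in_se_and_n(self):
        assert ci_from_se(2.0, 7) > ci_from_se(1.0, 7)
        assert ci_from_se(1.0, 20) < ci_from_se(1.0, 7)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            ci_from_se(1.0, 1)


class TestRunOrderEffect:
    def test_null_effect_small(self):
        small = 0
        n_rep = 100
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            X = rng.standard_normal((35, 73))
            pct, _ = run_order_effect(X, np.arange(1, 36))
            small += pct < 5.0
        assert small >= 0.90 * n_rep

    def test_planted_drift_fraction_recovered(self):
        # drift amplitude set so that it carries 20% of each scaled column's
        # variance; the predictive component should report ~20%
        recovered = []
        for s in range(20):
            rng = np.random.default_rng(s)
            n, k = 35, 73
            r = np.arange(1, n + 1, dtype=float)
            rz = (r - r.mean()) / r.std(ddof=1)
            sigma = 1.0
            a = sigma * 0.5  # a^2 / (a^2 + sigma^2) = 0.2
            X = rz[:, None] * a + rng.normal(0, sigma, size=(n, k))
            pct, _ = run_order_effect(X, r)
            recovered.append(pct)
        assert abs(np.mean(recovered) - 20.0) < 5.0

    def test_affine_invariance(self, rng):
        X = rng.standard_normal((20, 10))
        r = np.arange(1, 21, dtype=float)
        p1, _ = run_order_effect(X, r)
        p2, _ = run_order_effect(X, 5.0 + 3.0 * r)
        assert abs(p1 - p2) < 1e-10

    def test_constant_run_order_rejected(self, rng):
        X = rng.standard_normal((10, 5))
        with pytest.raises(ValueError):
            run_order_effect(X, np.ones(10))


class TestContinuousOpls:
    def test_predict_scores_consistent_with_fit(self, rng):
        X = pd.DataFrame(rng.standard_normal((25, 8)))
        y = rng.standard_normal(25)
        m = fit_opls(X, y, n_orth=1)
        t = predict_scores(m, X)
        np.testing.assert_allclose(t.to_numpy(), m.t.to_numpy(), atol=1e-10)

    def test_negative_n_orth_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError):
            fit_opls(X, rng.standard_normal(10), n_orth=-1)
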