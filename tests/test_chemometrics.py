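import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from hsifuse.chemometrics import (GaussianClassPDF, PlsdaClassifier,
                                  RbfClassifier, apply_scaler, calibrate_pdf,
                                  crossval_perf, fit_plsda, fit_scaler,
                                  posterior_healthy, predict_proba,
                                  rbf_classifier, select_lv)
from hsifuse.datatypes import BRUISED, HEALTHY, SpectrumTable

from conftest import make_separable_table


def table_from(X, labels=None, wl=None):
    X = np.asarray(X, float)
    if wl is None:
        wl = np.linspace(500, 900, X.shape[1])
    return SpectrumTable(X, wl, [f"s{i}" for i in range(X.shape[0])],
                        labels=labels)


class TestScaler:
    def test_two_point_column(self):
        t = table_from([[1.0, 0.0], [3.0, 1.0]])
        out = apply_scaler(fit_scaler(t), t)
        # sd uses the n-1 denominator
        np.testing.assert_allclose(out.values[:, 0],
                                   [-1 / np.sqrt(2), 1 / np.sqrt(2)],
                                   atol=1e-12)

    def test_training_transform_centered(self):
        rng = np.random.default_rng(1)
        t = table_from(rng.random((20, 5)))
        out = apply_scaler(fit_scaler(t), t)
        assert np.max(np.abs(out.values.mean(axis=0))) < 1e-12
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0,
                                   atol=1e-12)

    def test_constant_column_clamped_with_warning(self):
        t = table_from([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.warns(UserWarning, match="constant"):
            scaler = fit_scaler(t)
        out = apply_scaler(scaler, t)
        np.testing.assert_allclose(out.values[:, 1], 0.0, atol=1e-12)

    def test_needs_two_rows(self):
        with pytest.raises(ValueError, match="2 training rows"):
            fit_scaler(table_from([[1.0, 2.0]]))


class TestFitPlsda:
    def test_collinear_column_exact_fit(self):
        """A column equal to the class code is reproduced to 1e-6."""
        labels = np.array([HEALTHY, BRUISED] * 10)
        X = np.tile(labels.astype(float)[:, None], (1, 3))
        X[:, 1] = 0.5  # constant filler column
        X[:, 2] = 0.25
        t = table_from(X + 0, labels)
        model = fit_plsda(t, n_lv=1)
        np.testing.assert_allclose(model.predict_score(t.values),
                                   labels.astype(float), atol=1e-6)
        assert np.all(np.sign(model.predict_score(t.values)) == labels)

    def test_full_lv_equals_ols(self):
        rng = np.random.default_rng(3)
        labels = np.array([HEALTHY, BRUISED] * 15)
        X = rng.standard_normal((30, 6))
        t = table_from(X, labels)
        model = fit_plsda(t, n_lv=6)
        design = np.column_stack([np.ones(30), X])
        beta = np.linalg.lstsq(design, labels.astype(float), rcond=None)[0]
        np.testing.assert_allclose(model.predict_score(X), design @ beta,
                                   atol=1e-8)

    def test_matches_sklearn_pls(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(5)
        labels = np.array([HEALTHY, BRUISED] * 20)
        X = rng.standard_normal((40, 12))
        t = table_from(X, labels)
        for lv in (1, 3, 5):
            model = fit_plsda(t, n_lv=lv)
            sk = PLSRegression(n_components=lv, scale=False).fit(
                X, labels.astype(float))
            np.testing.assert_allclose(model.predict_score(X),
                                       sk.predict(X).ravel(), atol=1e-8)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(7)
        labels = np.array([HEALTHY, BRUISED] * 10)
        X = rng.standard_normal((20, 5))
        t = table_from(X, labels)
        perm = rng.permutation(20)
        tp = table_from(X[perm], labels[perm])
        m1 = fit_plsda(t, n_lv=3)
        m2 = fit_plsda(tp, n_lv=3)
        np.testing.assert_allclose(m1.coef, m2.coef, atol=1e-10)

    def test_single_class_rejected(self):
        t = table_from(np.random.default_rng(0).random((6, 3)),
                       np.full(6, HEALTHY))
        with pytest.raises(ValueError, match="single class"):
            fit_plsda(t, n_lv=1)

    def test_lv_bounds_enforced(self, small_table):
        with pytest.raises(ValueError, match="n_lv"):
            fit_plsda(small_table, n_lv=0)
        with pytest.raises(ValueError, match="n_lv"):
            fit_plsda(small_table, n_lv=100)


class TestSelectLv:
    def test_max_lv_one_returns_one(self):
        t = make_separable_table(seed=0)
        assert select_lv(t, max_lv=1, folds=10, seed=0) == 1

    def test_same_seed_same_answer(self):
        t = make_separable_table(seed=1)
        a = select_lv(t, max_lv=5, folds=10, seed=3)
        b = select_lv(t, max_lv=5, folds=10, seed=3)
        assert a == b

    def test_one_informative_direction_mostly_selects_one(self):
        hits = 0
        for seed in range(10):
            t = make_separable_table(n_per_class=40, p=10, delta=2.0,
                                     noise=0.25, seed=seed)
            if select_lv(t, max_lv=5, folds=10, seed=seed) == 1:
                hits += 1
        assert hits >= 8

    def test_too_few_samples_rejected(self):
        t = make_separable_table(n_per_class=3, seed=0)
        with pytest.raises(ValueError, match="fold"):
            select_lv(t, max_lv=2, folds=10, seed=0)


class TestCalibratePdf:
    def test_symmetric_cutoff_at_zero(self):
        scores = [0.8, 1.2, -0.8, -1.2]
        labels = [HEALTHY, HEALTHY, BRUISED, BRUISED]
        pdf = calibrate_pdf(scores, labels)
        assert pdf.mu_h == pytest.approx(1.0)
        assert pdf.mu_b == pytest.approx(-1.0)
        assert pdf.cutoff == pytest.approx(0.0, abs=1e-12)

    def test_unequal_sigma_root_matches_numeric_solver(self):
        # mu_h=1, sigma_h=1, mu_b=-1, sigma_b=2: root of equal densities
        rng = np.random.default_rng(0)
        sh = rng.normal(1.0, 1.0, 20000)
        sb = rng.normal(-1.0, 2.0, 20000)
        scores = np.concatenate([sh, sb])
        labels = np.concatenate([np.full(20000, HEALTHY),
                                 np.full(20000, BRUISED)])
        pdf = calibrate_pdf(scores, labels)

        def diff(y):
            return (norm.pdf(y, pdf.mu_h, pdf.sigma_h)
                    - norm.pdf(y, pdf.mu_b, pdf.sigma_b))

        root = brentq(diff, pdf.mu_b, pdf.mu_h)
        assert pdf.cutoff == pytest.approx(root, abs=1e-9)

    def test_posterior_half_at_cutoff(self):
        pdf = calibrate_pdf([0.5, 1.5, 0.9, -0.4, -1.1, -0.9],
                            [HEALTHY] * 3 + [BRUISED] * 3)
        assert posterior_healthy(pdf, pdf.cutoff) == pytest.approx(0.5,
                                                                   abs=1e-12)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            calibrate_pdf([1.0, -1.0, -0.9], [HEALTHY, BRUISED, BRUISED])

    def test_zero_sigma_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="floor"):
            pdf = calibrate_pdf([1.0, 1.0, -1.0, -1.0],
                                [HEALTHY, HEALTHY, BRUISED, BRUISED])
        assert pdf.sigma_h >= 1e-6


class TestPredictProba:
    def make_fitted(self):
        t = make_separable_table(seed=0)
        clf = PlsdaClassifier(n_lv=2, seed=0).fit(t)
        return clf, t

    def test_probabilities_normalized(self):
        clf, t = self.make_fitted()
        out = clf.predict_proba(t)
        np.testing.assert_allclose(out.proba.sum(axis=1), 1.0, atol=1e-12)

    def test_symmetric_pdf_midpoint_is_half_and_bruised(self):
        pdf = GaussianClassPDF(mu_h=1, sigma_h=1, mu_b=-1, sigma_b=1,
                               cutoff=0.0)
        ph = posterior_healthy(pdf, 0.0)
        assert ph == pytest.approx(0.5, abs=1e-12)
        # tie rule: p=0.5 -> bruised
        from hsifuse.chemometrics import _labels_from_p_healthy

        assert _labels_from_p_healthy(np.array([0.5]))[0] == BRUISED

    def test_score_at_class_mean_confident(self):
        pdf = GaussianClassPDF(mu_h=1, sigma_h=0.3, mu_b=-1, sigma_b=0.3,
                               cutoff=0.0)
        assert posterior_healthy(pdf, 1.0) > 0.5

    def test_monotone_between_means_equal_sigma(self):
        pdf = GaussianClassPDF(mu_h=1, sigma_h=0.5, mu_b=-1, sigma_b=0.5,
                               cutoff=0.0)
        ys = np.linspace(-1, 1, 50)
        ph = posterior_healthy(pdf, ys)
        assert np.all(np.diff(ph) > 0)

    def test_cutoff_consistency_with_argmax(self):
        clf, t = self.make_fitted()
        out = clf.predict_proba(t)
        assert np.all(
            (out.labels == HEALTHY) == (out.p_healthy > 0.5))

    def test_wavelength_mismatch_rejected(self):
        clf, t = self.make_fitted()
        other = table_from(t.values[:, :10], wl=np.linspace(100, 200, 10))
        with pytest.raises(ValueError, match="grid"):
            clf.predict_proba(other)


class TestCrossvalPerf:
    def test_perfect_classifier(self):
        t = make_separable_table(n_per_class=50, p=3, delta=6.0, noise=0.02,
                                 seed=0)
        perf = crossval_perf(PlsdaClassifier(n_lv=1, seed=0), t, seed=0)
        assert perf.sensitivity == 1.0 and perf.specificity == 1.0

    def test_constant_bruised_classifier(self):
        class AlwaysBruised:
            def clone(self):
                return self

            def fit(self, table):
                return self

            def predict_proba(self, table):
                from hsifuse.chemometrics import ProbOutput

                n = table.n_samples
                return ProbOutput(list(table.sample_ids),
                                  np.tile([0.0, 1.0], (n, 1)),
                                  np.full(n, BRUISED))

        t = make_separable_table(seed=1)
        perf = crossval_perf(AlwaysBruised(), t, seed=0)
        assert perf.sensitivity == 1.0 and perf.specificity == 0.0

    def test_label_permutation_near_chance(self):
        rng = np.random.default_rng(0)
        t = make_separable_table(n_per_class=100, delta=1.5, seed=0)
        permuted = SpectrumTable(t.values, t.wavelengths, t.sample_ids,
                                 labels=rng.permutation(t.labels))
        perf = crossval_perf(PlsdaClassifier(n_lv=2, seed=0), permuted,
                             seed=0)
        acc = (perf.sensitivity + perf.specificity) / 2
        # 3-sigma binomial band around 0.5 at n=200
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / 200) + 0.05


class TestRbfClassifier:
    def test_separable_blobs_high_cv_accuracy(self):
        t = make_separable_table(n_per_class=40, delta=2.0, noise=0.2, seed=0)
        clf = RbfClassifier(c_grid=(1.0, 10.0), g_grid=(0.01, 0.1), seed=0)
        perf = crossval_perf(clf, t, seed=0)
        assert (perf.sensitivity + perf.specificity) / 2 >= 0.95

    def test_single_grid_point_returned(self):
        t = make_separable_table(seed=0)
        clf = rbf_classifier(t, c_grid=(4.0,), g_grid=(0.25,), seed=0)
        assert clf.best_c_ == 4.0 and clf.best_g_ == 0.25

    def test_same_seed_same_hyperparams(self):
        t = make_separable_table(n_per_class=30, delta=0.8, noise=0.5, seed=2)
        grids = dict(c_grid=(0.5, 2.0, 8.0), g_grid=(0.05, 0.5))
        a = rbf_classifier(t, seed=5, **grids)
        b = rbf_classifier(t, seed=5, **grids)
        assert (a.best_c_, a.best_g_) == (b.best_c_, b.best_g_)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            RbfClassifier(c_grid=(), g_grid=(1.0,))

    def test_probability_contract(self):
        t = make_separable_table(seed=0)
        clf = rbf_classifier(t, c_grid=(1.0,), g_grid=(0.1,), seed=0)
        out = clf.predict_proba(t)
        np.testing.assert_allclose(out.proba.sum(axis=1), 1.0, atol=1e-9)


class TestParameterRecovery:
    def test_high_snr_cv_accuracy(self):
        """Strong effect vs noise: PLS-DA 10-fold CV accuracy >= 0.95."""
        from hsifuse.synth import SyntheticConfig, generate_mean_spectra

        cfg = SyntheticConfig(n_healthy=60, n_bruised=60, seed=3,
                              effect_size=0.2, latent_sd=0.1,
                              noise_sd_pb=0.005, noise_sd_lctf=0.004,
                              severity=1.0, calyx_fraction=0.0)
        tabA, _, _ = generate_mean_spectra(cfg)
        perf = crossval_perf(PlsdaClassifier(seed=0), tabA, seed=0)
        assert (perf.sensitivity + perf.specificity) / 2 >= 0.95


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        from hsifuse.chemometrics import load_plsda, save_plsda

        t = make_separable_table(seed=0)
        clf = PlsdaClassifier(n_lv=2, seed=0).fit(t)
        path = tmp_path / "model.json"
        save_plsda(path, clf)
        back = load_plsda(path)
        out1 = clf.predict_proba(t)
        out2 = back.predict_proba(t)
        np.testing.assert_allclose(out1.proba, out2.proba, atol=1e-12)
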