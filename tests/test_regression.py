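import numpy as np
import pandas as pd
import pytest

from kneeqs.predictors import BasisSpec, design_matrix
from kneeqs.regression import (SingularDesignError, fit_ols, flag_outliers,
                               mean_pct_error, pls_loso_cv, stepwise_backward)


def nipals_pls1_predict(Xtr, ytr, Xte, k):
    """Independent PLS1 (NIPALS on z-scored data) used as a refit oracle."""
    xm, xs = Xtr.mean(0), Xtr.std(0, ddof=1)
    ym, ys = ytr.mean(), ytr.std(ddof=1)
    Xd = (Xtr - xm) / xs
    yd = (ytr - ym) / ys
    W, P, Q = [], [], []
    for _ in range(k):
        w = Xd.T @ yd
        w /= np.linalg.norm(w)
        t = Xd @ w
        tt = t @ t
        p = Xd.T @ t / tt
        q = (yd @ t) / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - t * q
        W.append(w), P.append(p), Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    B = W @ np.linalg.solve(P.T @ W, Q)
    return ym + ys * (((Xte - xm) / xs) @ B)


class TestFitOLS:
    def test_exact_recovery_without_noise(self):
        x1 = np.linspace(0, 1, 30)
        X = pd.DataFrame({"x1": x1})
        y = 2.0 * x1 + 3.0
        m = fit_ols(X, y)
        assert m.coefficients["intercept"] == pytest.approx(3.0, rel=1e-10)
        assert m.coefficients["x1"] == pytest.approx(2.0, rel=1e-10)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = rng.normal(size=30)
        m = fit_ols(X, y)
        A = np.column_stack([np.ones(30), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        for est, ref in zip(
                [m.coefficients[k] for k in ["intercept", "a", "b", "c"]], beta):
            assert est == pytest.approx(ref, rel=1e-10, abs=1e-10)

    def test_duplicated_column_is_singular(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": rng.normal(size=20), "a_copy": x})
        with pytest.raises(SingularDesignError, match="a_copy"):
            fit_ols(X, rng.normal(size=20))


class TestStepwiseBackward:
    def test_all_noise_gives_intercept_only(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = 5.0 + rng.normal(size=60)
        with pytest.warns(UserWarning, match="intercept-only"):
            m = stepwise_backward(X, y)
        assert m.retained_terms == []
        assert m.coefficients["intercept"] == pytest.approx(y.mean())

    def test_stopping_condition_all_retained_significant(self, default_run,
                                                         default_summary_frame):
        _, dataset, _, _ = default_run
        basis = BasisSpec.default()
        X, y, _ = design_matrix(dataset.subjects, default_summary_frame,
                                "K_flex", basis)
        m = stepwise_backward(X, y, alpha=0.05, basis=basis)
        assert m.retained_terms
        assert max(m.p_values[t] for t in m.retained_terms) <= 0.05
        # the intercept is reported even when not significant, never dropped
        assert "intercept" in m.p_values


class TestPLS:
    def test_one_component_single_predictor_equals_univariate_ols(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        y = 2.0 * x + rng.normal(scale=0.3, size=40)
        groups = np.arange(40) % 4
        rep = pls_loso_cv(pd.DataFrame({"x": x}), y, groups, max_components=1)
        press_ols = 0.0
        for g in range(4):
            te = groups == g
            b, a = np.polyfit(x[~te], y[~te], 1)
            press_ols += np.sum((y[te] - (a + b * x[te])) ** 2)
        assert rep.press_by_components[0] == pytest.approx(press_ols, rel=1e-10)

    def test_press_matches_per_fold_refit_oracle(self):
        rng = np.random.default_rng(8)
        n, p = 60, 7
        X = rng.normal(size=(n, p))
        X[:, 3] = 0.9 * X[:, 0] + 0.1 * rng.normal(size=n)
        y = 2 * X[:, 0] + X[:, 1] - X[:, 4] + 0.3 * rng.normal(size=n)
        groups = np.arange(n) % 6
        rep = pls_loso_cv(pd.DataFrame(X), y, groups)
        for k in range(1, p + 1):
            press_k = 0.0
            for g in range(6):
                te = groups == g
                press_k += np.sum(
                    (y[te] - nipals_pls1_predict(X[~te], y[~te], X[te], k)) ** 2)
            assert rep.press_by_components[k - 1] == pytest.approx(
                press_k, rel=1e-8)
        assert rep.n_components_optimal == int(np.argmin(rep.press_by_components)) + 1

    def test_press_invariant_to_ordering_and_relabeling(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(60, 5)))
        y = 3.0 * X.iloc[:, 0].to_numpy() + 0.5 * rng.normal(size=60)
        g = np.repeat(np.arange(6), 10)
        base = pls_loso_cv(X, y, g)
        perm = rng.permutation(60)
        shuffled = pls_loso_cv(X.iloc[perm].reset_index(drop=True), y[perm],
                               g[perm])
        relabeled = pls_loso_cv(X, y, np.array([f"subj{5 - v}" for v in g]))
        np.testing.assert_allclose(base.press_by_components,
                                   shuffled.press_by_components, rtol=1e-10)
        np.testing.assert_allclose(base.press_by_components,
                                   relabeled.press_by_components, rtol=1e-12)

    def test_two_latent_directions_recovered(self):
        """Optimal component count is 2 when y is driven by exactly two
        independent latent factors observed in two predictor blocks."""
        hits = 0
        n, p, ng = 136, 7, 14
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t1, t2 = rng.normal(size=n), rng.normal(size=n)
            X = np.empty((n, p))
            for j in range(p):
                X[:, j] = (t1 if j < 3 else t2) + 0.7 * rng.normal(size=n)
            y = 2 * t1 - 2 * t2 + 0.4 * rng.normal(size=n)
            rep = pls_loso_cv(pd.DataFrame(X), y, np.arange(n) % ng)
            hits += rep.n_components_optimal == 2
        assert hits >= 45  # >= 90% of 50 seeds

    def test_cv_predicted_r2_not_above_training_r2(self, default_run,
                                                   default_summary_frame):
        _, dataset, _, _ = default_run
        X, y, groups = design_matrix(dataset.subjects, default_summary_frame,
                                     "K_wa", BasisSpec.default())
        rep = pls_loso_cv(X, y, groups)
        insample = fit_ols(X, y).r2 * 100.0
        assert rep.cv_predicted_r2 <= insample + 1e-9


class TestErrorMetrics:
    def test_perfect_predictions(self):
        y = np.array([100.0, 200.0, 300.0])
        assert mean_pct_error(y, y) == 0.0

    def test_uniform_ten_percent(self):
        y = np.array([100.0, 200.0, 300.0])
        assert mean_pct_error(y, 1.1 * y) == pytest.approx(10.0)

    def test_matches_hand_loop(self):
        y = np.array([120.0, 250.0, 310.0, 95.0, 400.0])
        yhat = np.array([130.0, 240.0, 330.0, 100.0, 380.0])
        expected = 100.0 * np.mean([abs(a - b) / b for a, b in zip(yhat, y)])
        assert mean_pct_error(y, yhat) == pytest.approx(expected, rel=1e-12)

    def test_zero_observed_excluded_with_warning(self):
        y = np.array([0.0, 100.0])
        with pytest.warns(UserWarning, match="observed == 0"):
            assert mean_pct_error(y, np.array([10.0, 110.0])) == pytest.approx(10.0)


class TestOutliers:
    def _fit(self, dataset, sdf):
        X, y, _ = design_matrix(dataset.subjects, sdf, "K_flex",
                                BasisSpec.default())
        return X, y

    def test_noiseless_data_has_no_outliers(self, noiseless_run):
        _, dataset, _, summaries = noiseless_run
        sdf = pd.DataFrame([vars(s) for s in summaries])
        X, y = self._fit(dataset, sdf)
        m = fit_ols(X, y)
        assert flag_outliers(m, X, y) == []

    def test_planted_outlier_is_flagged(self, default_run,
                                        default_summary_frame):
        _, dataset, _, _ = default_run
        sdf = default_summary_frame.copy()
        victim = sdf.loc[10, "trial_id"]
        sdf.loc[10, "K_flex"] *= 5.0
        X, y = self._fit(dataset, sdf)
        m = fit_ols(X, y)
        assert victim in flag_outliers(m, X, y)

    def test_infinite_threshold_flags_nothing(self, default_run,
                                              default_summary_frame):
        _, dataset, _, _ = default_run
        X, y = self._fit(dataset, default_summary_frame)
        m = fit_ols(X, y)
        assert flag_outliers(m, X, y, threshold=np.inf) == []
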