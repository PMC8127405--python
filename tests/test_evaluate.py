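import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gers.evaluate import (CvScheme, DegeneratePredictorError, ScorePredictor,
                           best_single_column, corr_with_se, fit_elastic_net,
                           fit_single, williams_test)


class TestCorrWithSe:
    def test_identical_and_anti_identical(self):
        x = np.arange(10, dtype=float)
        r, se, n = corr_with_se(x, x)
        assert r == pytest.approx(1.0) and se == pytest.approx(0.0, abs=1e-6)
        r, _, _ = corr_with_se(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        r, se, n = corr_with_se(x, y)
        # definition oracle
        xc, yc = x - x.mean(), y - y.mean()
        r0 = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert r == pytest.approx(r0, abs=1e-12)
        assert se == pytest.approx(np.sqrt((1 - r0 ** 2) / 8), abs=1e-12)

    def test_degenerate(self):
        with pytest.raises(DegeneratePredictorError):
            corr_with_se(np.ones(10), np.arange(10.0))


def _williams_oracle(r12, r13, r23, n):
    """Second, independently written Hotelling-Williams implementation
    (determinant form written out term by term)."""
    detR = 1.0 - r12 * r12 - r13 * r13 - r23 * r23 + 2.0 * r12 * r13 * r23
    rbar = 0.5 * (r12 + r13)
    t = (r12 - r13) * np.sqrt(
        ((n - 1.0) * (1.0 + r23))
        / (2.0 * detR * (n - 1.0) / (n - 3.0)
           + rbar * rbar * (1.0 - r23) ** 3))
    return t, 2 * stats.t.sf(abs(t), n - 3)


class TestWilliams:
    def test_equal_correlations(self):
        t, p = williams_test(0.3, 0.3, 0.5, 100)
        assert t == 0.0 and p == 1.0

    def test_fixed_case_against_independent_formula(self):
        t, p = williams_test(0.5, 0.4, 0.8, 103)
        t0, p0 = _williams_oracle(0.5, 0.4, 0.8, 103)
        assert t == pytest.approx(t0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)

    def test_power_grows_with_prediction_overlap(self):
        ts = [abs(williams_test(0.5, 0.4, r_ab, 200)[0])
              for r_ab in (0.1, 0.5, 0.9, 0.97)]
        assert ts == sorted(ts)

    def test_fixed_case_against_permutation_oracle(self):
        """On one dataset, the Williams P agrees with a label-swap
        permutation test (swap the two predictors per-sample at random)."""
        rng = np.random.default_rng(12)
        n = 300
        g = rng.standard_normal(n)
        y = g + rng.standard_normal(n)
        a = g + 0.6 * rng.standard_normal(n)
        b = g + 1.3 * rng.standard_normal(n)   # weaker predictor
        r_ay = np.corrcoef(a, y)[0, 1]
        r_by = np.corrcoef(b, y)[0, 1]
        r_ab = np.corrcoef(a, b)[0, 1]
        t_obs, p_obs = williams_test(r_ay, r_by, r_ab, n)
        stat = abs(r_ay - r_by)
        null = []
        for _ in range(2000):
            swap = rng.random(n) < 0.5
            a2 = np.where(swap, b, a)
            b2 = np.where(swap, a, b)
            null.append(abs(np.corrcoef(a2, y)[0, 1]
                            - np.corrcoef(b2, y)[0, 1]))
        p_perm = (1 + sum(s >= stat for s in null)) / 2001
        assert p_obs == pytest.approx(p_perm, abs=0.03)

    def test_non_pd_correlations_rejected(self):
        with pytest.raises(FloatingPointError):
            williams_test(0.9, -0.9, 0.9, 100)

    def test_null_calibration(self):
        """Two equally predictive scores, n=500, 1000 replicates: the 0.05
        rejection rate lies in the exact binomial 99% interval."""
        rng = np.random.default_rng(2024)
        n, reps, alpha = 500, 1000, 0.05
        rejections = 0
        for _ in range(reps):
            g = rng.standard_normal(n)
            y = g + rng.standard_normal(n)
            a = g + rng.standard_normal(n)
            b = g + rng.standard_normal(n)
            _, p = williams_test(np.corrcoef(a, y)[0, 1],
                                 np.corrcoef(b, y)[0, 1],
                                 np.corrcoef(a, b)[0, 1], n)
            rejections += p < alpha
        lo = stats.binom.ppf(0.005, reps, alpha)
        hi = stats.binom.ppf(0.995, reps, alpha)
        assert lo <= rejections <= hi


class TestFitSingle:
    def test_perfect_predictor(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(200)
        preds = fit_single(y, y, "continuous", CvScheme(seed=1))
        r, _, _ = corr_with_se(preds, y)
        assert r == pytest.approx(1.0)

    def test_null_predictor(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(5000)
        x = rng.standard_normal(5000)
        preds = fit_single(x, y, "continuous", CvScheme(seed=2))
        r, _, _ = corr_with_se(preds, y)
        assert abs(r) < 0.05

    def test_matches_closed_form_least_squares(self):
        """Out-of-fold predictions equal normal-equation OLS fitted on each
        training fold."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10)
        y = 2 * x + rng.standard_normal(10)
        scheme = CvScheme(outer_k=2, seed=3)
        preds = fit_single(x, y, "continuous", scheme)
        from sklearn.model_selection import KFold
        for tr, te in KFold(2, shuffle=True, random_state=3).split(x):
            X1 = np.column_stack([np.ones(tr.size), x[tr]])
            beta = np.linalg.solve(X1.T @ X1, X1.T @ y[tr])
            np.testing.assert_allclose(preds[te], beta[0] + beta[1] * x[te],
                                       atol=1e-10)

    def test_binary_uses_logistic_linear_predictor(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(400)
        y = (rng.random(400) < 1 / (1 + np.exp(-2 * x))).astype(float)
        preds = fit_single(x, y, "binary", CvScheme(seed=4))
        r, _, _ = corr_with_se(preds, y)
        assert r > 0.3

    def test_constant_column_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            fit_single(np.ones(100), np.random.default_rng(0).standard_normal(100),
                       "continuous")


class TestElasticNet:
    def test_redundant_duplicates_match_single(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(1500)
        y = x + rng.standard_normal(1500)
        single = fit_single(x, y, "continuous", CvScheme(seed=5))
        r1, _, _ = corr_with_se(single, y)
        dup = pd.DataFrame({f"c{i}": x for i in range(16)})
        preds = fit_elastic_net(dup, y, "continuous", CvScheme(seed=5))
        r16, _, _ = corr_with_se(preds, y)
        assert r16 == pytest.approx(r1, abs=0.02)

    def test_oracle_column_dominates_noise(self):
        rng = np.random.default_rng(6)
        n = 5000
        y = rng.standard_normal(n)
        cols = {"signal": y.copy()}
        for i in range(10):
            cols[f"noise{i}"] = rng.standard_normal(n)
        preds = fit_elastic_net(pd.DataFrame(cols), y, "continuous",
                                CvScheme(seed=6))
        r, _, _ = corr_with_se(preds, y)
        assert r > 0.99

    def test_coverage(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((300, 4)))
        X.columns = [f"s{i}" for i in range(4)]
        y = rng.standard_normal(300)
        preds = fit_elastic_net(X, y, "continuous", CvScheme(seed=7))
        assert not np.isnan(preds).any()   # every sample predicted once

    def test_no_leakage_under_test_fold_permutation(self):
        """Permuting the phenotype inside one held-out fold does not change
        that fold's predictions."""
        rng = np.random.default_rng(8)
        n = 400
        X = pd.DataFrame(rng.standard_normal((n, 5)),
                         columns=[f"s{i}" for i in range(5)])
        y = X["s0"].to_numpy() + rng.standard_normal(n)
        scheme = CvScheme(seed=8)
        from sklearn.model_selection import KFold
        folds = list(KFold(5, shuffle=True, random_state=8).split(X, y))
        test_idx = folds[2][1]
        y_perm = y.copy()
        y_perm[test_idx] = rng.permutation(y[test_idx])
        p0 = fit_elastic_net(X, y, "continuous", scheme)
        p1 = fit_elastic_net(X, y_perm, "continuous", scheme)
        np.testing.assert_array_equal(p0[test_idx], p1[test_idx])


class TestModelObjects:
    def test_fit_and_compare_self(self):
        rng = np.random.default_rng(9)
        s = pd.DataFrame({"a": rng.standard_normal(300)})
        y = s["a"].to_numpy() + rng.standard_normal(300)
        res = ScorePredictor(s, y, name="m").fit(CvScheme(seed=9))
        cmp = res.compare(res)
        assert cmp["rel_improvement"] == 0.0
        assert cmp["p_two_sided"] == 1.0
        assert cmp["ratio"] == pytest.approx(1.0)
        assert "predicted-observed r" in res.summary()

    def test_keyed_join_from_score_matrix(self):
        from gers.scoring import ScoreMatrix
        rng = np.random.default_rng(10)
        samples = pd.DataFrame({"FID": ["a", "b", "c", "d"] * 25,
                                "IID": [f"i{k}" for k in range(100)]})
        sm = ScoreMatrix(samples,
                         pd.DataFrame({"s": rng.standard_normal(100)}))
        pheno = pd.concat([samples, pd.Series(rng.standard_normal(100),
                                              name="PHENO")], axis=1)
        shuffled = pheno.sample(frac=1, random_state=1)
        m = ScorePredictor.from_score_matrix(sm, shuffled, name="m")
        assert len(m.phenotype) == 100

    def test_best_single_column(self):
        rng = np.random.default_rng(11)
        y = rng.standard_normal(500)
        scores = pd.DataFrame({"good": y + 0.3 * rng.standard_normal(500),
                               "bad": rng.standard_normal(500)})
        name, res = best_single_column(scores, y, scheme=CvScheme(seed=11))
        assert name == "good"
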