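import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from seqdx.exceptions import ConfigurationError, DegenerateDataError
from seqdx.expression import ExpressionMatrix
from seqdx.markers import (ModelSpec, auc_score, default_lambda_grid, delong_compare,
                           delong_auc_variance, fit_elastic_net,
                           fit_single_gene_logistic, nested_cv_scores,
                           optimal_boundary, roc_points, RocCurve)


def brute_force_auc(scores, labels):
    """Pair-counting oracle: fraction of (pos, neg) pairs ranked correctly,
    0.5 credit for ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestSingleGeneLogistic:
    def test_constant_predictor_degenerates_to_prevalence(self):
        y = np.array([1] * 3 + [0] * 7)
        model = fit_single_gene_logistic(np.full(10, 5.0), y)
        assert model.slope == pytest.approx(0.0, abs=1e-6)
        assert model.intercept == pytest.approx(logit(0.3), abs=1e-6)

    def test_probability_half_at_symmetry_midpoint(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 7.0, 8.0, 9.0])
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1])  # anti-symmetric around 5
        model = fit_single_gene_logistic(x, y)
        assert model.predict_proba([5.0])[0] == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_irls(self, seed):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 20)
        y = (rng.random(20) < 1 / (1 + np.exp(-(0.5 + 1.5 * x)))).astype(int)
        if y.min() == y.max():
            pytest.skip("degenerate draw")
        model = fit_single_gene_logistic(x, y)
        fit = sm.Logit(y, np.column_stack([np.ones(20), x])).fit(disp=0)
        assert model.intercept == pytest.approx(fit.params[0], abs=1e-4)
        assert model.slope == pytest.approx(fit.params[1], abs=1e-4)

    def test_separable_data_yields_finite_estimates(self):
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_single_gene_logistic(x, y)
        assert np.isfinite(model.slope) and np.isfinite(model.intercept)
        assert model.slope > 0

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_single_gene_logistic(np.arange(6.0), np.ones(6))


class TestElasticNet:
    def test_full_shrinkage_limits(self, random_log2_matrix):
        m = random_log2_matrix(n_genes=8, n_samples=40, seed=4)
        rng = np.random.default_rng(4)
        y = (rng.random(40) < 0.4).astype(int)
        model = fit_elastic_net(m, y, family="binomial", lambda_grid=[1e6])
        assert np.all(model.coef == 0.0)
        assert model.intercept == pytest.approx(logit(y.mean()), abs=1e-6)
        yc = rng.normal(3.0, 1.0, 40)
        linear = fit_elastic_net(m, yc, family="linear", lambda_grid=[1e6])
        assert np.all(linear.coef == 0.0)
        assert linear.intercept == pytest.approx(yc.mean(), abs=1e-6)

    def test_zero_penalty_matches_ols(self, random_log2_matrix):
        m = random_log2_matrix(n_genes=6, n_samples=50, seed=5)
        rng = np.random.default_rng(5)
        beta = rng.normal(0, 1, 6)
        X = m.values.to_numpy().T
        yc = X @ beta + rng.normal(0, 0.1, 50)
        model = fit_elastic_net(m, yc, family="linear", lambda_grid=[0.0])
        design = np.column_stack([np.ones(50), X])
        ols = np.linalg.lstsq(design, yc, rcond=None)[0]
        np.testing.assert_allclose(np.concatenate([[model.intercept], model.coef]),
                                   ols, atol=1e-4)

    def test_recovers_causal_genes(self, random_log2_matrix):
        m = random_log2_matrix(n_genes=10, n_samples=100, seed=6)
        X = m.values.to_numpy().T
        rng = np.random.default_rng(6)
        yc = 2.0 * X[:, 1] - 2.0 * X[:, 7] + rng.normal(0, 0.5, 100)
        model = fit_elastic_net(m, yc, family="linear", inner_folds=5, seed=6,
                                n_lambda=30)
        assert model.coef[1] != 0.0 and model.coef[7] != 0.0

    def test_lambda_grid_descends_from_lambda_max(self, random_log2_matrix):
        m = random_log2_matrix(n_genes=5, n_samples=30, seed=7)
        y = np.random.default_rng(7).normal(0, 1, 30)
        grid = default_lambda_grid(m.values.to_numpy().T, y, "linear", 0.5,
                                   n_lambda=10)
        assert len(grid) == 10 and grid[0] > grid[-1]
        model = fit_elastic_net(m, y, family="linear", lambda_grid=[grid[0]])
        assert np.all(model.coef == 0.0)  # lambda_max zeroes every gene

    def test_too_few_samples_for_folds(self, random_log2_matrix):
        m = random_log2_matrix(n_genes=4, n_samples=3, seed=8)
        with pytest.raises(DegenerateDataError):
            fit_elastic_net(m, np.array([0.1, 0.5, 0.2]), family="linear",
                            lambda_grid=[0.1, 0.2], inner_folds=5)


class TestNestedCv:
    def test_each_sample_scored_exactly_once(self, random_log2_matrix):
        m = random_log2_matrix(n_genes=4, n_samples=10, seed=9)
        y = np.array([0, 1] * 5)
        scores, folds = nested_cv_scores(m, y, ModelSpec(kind="single_gene_logistic",
                                                         gene="g0"), outer_k=5)
        assert scores.notna().all()
        assert sorted(folds.value_counts().index) == [0, 1, 2, 3, 4]
        assert (folds.value_counts() == 2).all()

    def test_deterministic_given_seed(self, random_log2_matrix):
        m = random_log2_matrix(n_genes=4, n_samples=30, seed=10)
        y = (np.random.default_rng(10).random(30) < 0.5).astype(int)
        a = nested_cv_scores(m, y, ModelSpec(kind="single_gene_logistic", gene="g1"),
                             seed=3)
        b = nested_cv_scores(m, y, ModelSpec(kind="single_gene_logistic", gene="g1"),
                             seed=3)
        pd.testing.assert_series_equal(a[0], b[0])
        pd.testing.assert_series_equal(a[1], b[1])

    def test_class_absent_from_fold_advises(self, random_log2_matrix):
        m = random_log2_matrix(n_genes=3, n_samples=12, seed=11)
        y = np.array([1] + [0] * 11)  # one positive cannot stratify over 5 folds
        with pytest.raises(DegenerateDataError, match="fewer folds|fold"):
            nested_cv_scores(m, y, ModelSpec(kind="single_gene_logistic", gene="g0"),
                             outer_k=5)


class TestRoc:
    def test_perfect_separation_contains_corner(self):
        curve = roc_points([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        pts = set(zip(curve.fpr, curve.tpr))
        assert (0.0, 1.0) in pts
        assert (0.0, 0.0) in pts and (1.0, 1.0) in pts

    def test_hand_enumerated_curve_point(self):
        curve = roc_points([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0])
        assert (0.5, 0.5) in set(zip(curve.fpr, curve.tpr))

    def test_monotone_endpoints(self):
        rng = np.random.default_rng(12)
        s = rng.normal(0, 1, 50)
        y = (rng.random(50) < 0.5).astype(int)
        curve = roc_points(s, y)
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1

    def test_spec_example_auc(self):
        assert auc_score([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_tied_pair_gets_half_credit(self):
        # one positive ties one negative; remaining pairs separated
        assert auc_score([0.9, 0.5, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.875)

    def test_score_reversal_mirrors_auc(self):
        rng = np.random.default_rng(13)
        s = rng.normal(0, 1, 40)  # continuous, tie-free
        y = (rng.random(40) < 0.4).astype(int)
        assert auc_score(s, y) + auc_score(-s, y) == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 1000), scale=st.floats(0.1, 10.0),
           shift=st.floats(-5.0, 5.0))
    def test_auc_invariant_under_increasing_transform(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        s = rng.normal(0, 1, 30)
        y = np.array([0, 1] * 15)
        transformed = np.exp(scale * s) + shift
        assert auc_score(s, y) == pytest.approx(auc_score(transformed, y), abs=1e-12)


class TestOptimalBoundary:
    def test_perfect_corner_selected(self):
        curve = roc_points([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        thr = optimal_boundary(curve)
        i = list(curve.thresholds).index(thr)
        assert (curve.fpr[i], curve.tpr[i]) == (0.0, 1.0)

    def test_three_point_distance_comparison(self):
        curve = RocCurve(thresholds=np.array([np.inf, 0.6, 0.1]),
                         fpr=np.array([0.0, 0.2, 1.0]),
                         tpr=np.array([0.0, 0.8, 1.0]))
        assert optimal_boundary(curve) == 0.6

    def test_tie_broken_toward_lower_fpr(self):
        # d2(0.1, 0.7) = 0.01 + 0.09 = 0.1 = d2(0.3, 0.9): exact tie
        curve = RocCurve(thresholds=np.array([np.inf, 0.7, 0.3, 0.0]),
                         fpr=np.array([0.0, 0.1, 0.3, 1.0]),
                         tpr=np.array([0.0, 0.7, 0.9, 1.0]))
        assert optimal_boundary(curve) == 0.7


class TestDeLong:
    def test_identical_cohorts_give_null_result(self):
        s = [0.9, 0.7, 0.4, 0.2]
        y = [1, 0, 1, 0]
        res = delong_compare(s, y, s, y)
        assert res.z == 0.0 and res.p_two_sided == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_delong_auc_equals_trapezoid(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        s = rng.normal(0, 1, n)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        auc, _ = delong_auc_variance(s, y)
        assert auc == pytest.approx(auc_score(s, y), abs=1e-12)

    def test_matches_r_proc_unpaired(self, tmp_path):
        rng = np.random.default_rng(7)
        ya = (rng.random(60) < 0.4).astype(int)
        sa = rng.normal(0, 1, 60) + 1.2 * ya
        yb = (rng.random(80) < 0.5).astype(int)
        sb = rng.normal(0, 1, 80) + 0.4 * yb
        res = delong_compare(sa, ya, sb, yb)
        pd.DataFrame({"y": ya, "s": sa}).to_csv(tmp_path / "a.csv", index=False)
        pd.DataFrame({"y": yb, "s": sb}).to_csv(tmp_path / "b.csv", index=False)
        script = f'''
suppressMessages(library(pROC))
a <- read.csv("{tmp_path}/a.csv"); b <- read.csv("{tmp_path}/b.csv")
ra <- roc(a$y, a$s, quiet=TRUE, direction="<")
rb <- roc(b$y, b$s, quiet=TRUE, direction="<")
t <- roc.test(ra, rb, method="delong", paired=FALSE)
cat(sprintf("%.12f %.12f %.12f", auc(ra), auc(rb), t$statistic))
'''
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        auc_a, auc_b, stat = map(float, proc.stdout.split())
        assert res.auc_a == pytest.approx(auc_a, abs=1e-10)
        assert res.auc_b == pytest.approx(auc_b, abs=1e-10)
        # pROC reports the same standardized statistic (its p uses a t
        # reference for unpaired cohorts; this package reports a normal p)
        assert res.z == pytest.approx(stat, abs=1e-9)

    def test_degenerate_zero_variance_rejected(self):
        # both cohorts perfectly separated (zero variance) with unequal AUCs
        with pytest.raises(DegenerateDataError):
            delong_compare([1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0],
                           [1.0, 1.0, 0.0, 0.0], [0, 0, 1, 1])
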