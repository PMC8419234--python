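"""Feature-table assembly, LASSO screening (with the soft-threshold and
glmnet oracles), normality routing, correlation, and descriptive summary."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from eeg2tms import (
    assemble_features,
    correlate,
    lasso_select,
    normality_route,
    summarize_cohort,
)
from eeg2tms.association import (
    AssociationError,
    feature_columns,
    fit_lasso_at,
    lambda_grid,
)


def soft_threshold(z, lam):
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def orthonormal_design(rng, n=64, p=8):
    """Columns with X.T @ X = n * I, the scaling under which the LASSO
    solution is coordinate-wise soft-thresholding of OLS."""
    q, _ = np.linalg.qr(rng.standard_normal((n, p)))
    return q * np.sqrt(n)


def make_tables(n=6, bands=("alpha1", "alpha2")):
    ids = pd.Index([f"sub-{i:03d}" for i in range(n)], name="subject_id")
    rng = np.random.default_rng(0)
    rp = pd.DataFrame({f"power_{b}": rng.uniform(0.5, 2, n) for b in bands},
                      index=ids)
    cols = [c for c in feature_columns(bands) if not c.startswith("power_")]
    na = pd.DataFrame({c: rng.uniform(0, 1, n) for c in cols}, index=ids)
    tg = pd.DataFrame({"RMT": rng.uniform(30, 60, n),
                       "AMT": rng.uniform(20, 40, n)}, index=ids)
    return rp, na, tg


class TestAssemble:
    def test_column_order_and_shape(self):
        rp, na, tg = make_tables()
        table = assemble_features(rp, na, tg)
        assert list(table.columns) == feature_columns(("alpha1", "alpha2")) + \
            ["RMT", "AMT"]
        assert len(table) == 6

    def test_thirty_predictors_for_six_bands(self):
        bands = ("delta", "theta", "alpha1", "alpha2", "beta1", "beta2")
        assert len(feature_columns(bands)) == 30

    def test_single_subject_table_is_valid(self):
        rp, na, tg = make_tables(n=1)
        assert len(assemble_features(rp, na, tg)) == 1

    def test_duplicate_subject_rejected(self):
        rp, na, tg = make_tables()
        rp_dup = pd.concat([rp, rp.iloc[[0]]])
        with pytest.raises(AssociationError, match="duplicated"):
            assemble_features(rp_dup, na, tg)

    def test_subject_mismatch_rejected(self):
        rp, na, tg = make_tables()
        with pytest.raises(AssociationError, match="sub-005"):
            assemble_features(rp, na.iloc[:-1], tg)

    def test_missing_value_rejected(self):
        rp, na, tg = make_tables()
        na.iloc[2, 0] = np.nan
        with pytest.raises(AssociationError, match="sub-002"):
            assemble_features(rp, na, tg)


class TestLassoCore:
    def test_above_lambda_max_all_zero(self, rng):
        X = orthonormal_design(rng)
        y = X @ np.array([2.0, 0, 0, -1.5, 0, 0, 0.5, 0]) + \
            rng.standard_normal(64)
        y = y - y.mean()
        lam_max = lambda_grid(X, y)[0]
        assert np.all(fit_lasso_at(X, y, lam_max * 1.001) == 0.0)

    def test_soft_threshold_closed_form(self, rng):
        X = orthonormal_design(rng)
        beta = np.array([3.0, -2.0, 0.0, 1.0, 0.0, 0.0, -0.5, 0.0])
        y = X @ beta + 0.3 * rng.standard_normal(64)
        y = y - y.mean()
        ols = X.T @ y / 64
        for lam in (0.05, 0.3, 1.0, 2.5):
            coef = fit_lasso_at(X, y, lam)
            assert np.max(np.abs(coef - soft_threshold(ols, lam))) < 1e-6

    def test_selection_nested_along_path_on_orthonormal_design(self, rng):
        X = orthonormal_design(rng)
        y = X @ np.array([3.0, -2.0, 0, 1.0, 0, 0, -0.5, 0])
        grid = lambda_grid(X, y, n_lambdas=30)
        prev: set = set()
        for lam in grid:  # descending -> growing support
            sel = set(np.flatnonzero(fit_lasso_at(X, y, lam)))
            assert prev <= sel
            prev = sel

    def test_matches_glmnet_at_fixed_lambda(self, rng, tmp_path):
        """Independent cross-check against the R reference implementation
        of coordinate-descent LASSO (same 1/(2n) objective scaling)."""
        X = orthonormal_design(rng, n=40, p=5)
        y = X @ np.array([2.0, 0.0, -1.0, 0.0, 0.5])
        y = y - y.mean()
        lam = 0.4
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        np.savetxt(tmp_path / "y.csv", y, delimiter=",")
        script = textwrap.dedent(f"""
            suppressMessages(library(glmnet))
            X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE))
            y <- scan("{tmp_path}/y.csv", quiet=TRUE)
            fit <- glmnet(X, y, lambda={lam}, standardize=FALSE,
                          intercept=FALSE, thresh=1e-12)
            cat(as.numeric(coef(fit))[-1], sep=",")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        r_coef = np.array([float(v) for v in out.stdout.split(",")])
        assert np.max(np.abs(fit_lasso_at(X, y, lam) - r_coef)) < 1e-6


class TestLassoSelect:
    def cohort(self, rng, n=60, signal=-6.0, noise=1.0):
        bands = ("delta", "theta", "alpha1", "alpha2", "beta1", "beta2")
        cols = feature_columns(bands)
        X = rng.uniform(0, 1, size=(n, len(cols)))
        ids = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
        table = pd.DataFrame(X, columns=cols, index=ids)
        z = (table["power_alpha2"] - table["power_alpha2"].mean()) \
            / table["power_alpha2"].std(ddof=0)
        table["RMT"] = 46.0 + signal * z + noise * rng.standard_normal(n)
        table["AMT"] = 32.0 + signal * z + noise * rng.standard_normal(n)
        return table

    def test_strong_predictor_selected(self, rng):
        fit = lasso_select(self.cohort(rng), "RMT", seed=1)
        assert "power_alpha2" in fit.selected
        assert fit.lambda_min in fit.lambdas
        assert fit.cv_mse[fit.lambdas == fit.lambda_min] == fit.cv_mse.min()

    def test_selected_set_is_nonzero_coefficients(self, rng):
        fit = lasso_select(self.cohort(rng), "AMT", seed=1)
        nonzero = {k for k, v in fit.coef_standardized.items() if v != 0}
        assert set(fit.selected) == nonzero

    def test_too_few_subjects_rejected(self, rng):
        table = self.cohort(rng, n=10)
        with pytest.raises(AssociationError, match="10-fold"):
            lasso_select(table, "RMT", folds=10)

    def test_constant_predictor_dropped_with_warning(self, rng):
        table = self.cohort(rng)
        table["power_delta"] = 1.0
        with pytest.warns(UserWarning, match="power_delta"):
            fit = lasso_select(table, "RMT", seed=1)
        assert "power_delta" in fit.dropped_constant
        assert "power_delta" not in fit.coef_standardized


class TestNormalityRouting:
    def test_gaussian_pair_routes_to_pearson(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        method, xn, yn = normality_route(x, y)
        assert method == "pearson" and xn and yn

    def test_exponential_sample_routes_to_spearman(self, rng):
        x = rng.standard_normal(100)
        y = rng.exponential(size=100)
        method, _, yn = normality_route(x, y)
        assert method == "spearman" and not yn

    def test_tiny_sample_rejected(self):
        with pytest.raises(AssociationError):
            normality_route([1.0, 2.0], [3.0, 4.0])

    def test_constant_sample_warns_and_routes_spearman(self, rng):
        x = rng.standard_normal(20)
        with pytest.warns(UserWarning, match="constant"):
            method, _, _ = normality_route(x, np.ones(20))
        assert method == "spearman"


class TestCorrelate:
    def test_perfect_linear_pearson(self, rng):
        x = rng.standard_normal(50)
        r = correlate(x, 2 * x + 1, method="pearson")
        assert r.coefficient == pytest.approx(1.0)
        assert r.p_value < 1e-20

    def test_monotone_nonlinear_spearman(self, rng):
        x = rng.standard_normal(50)
        r = correlate(x, np.exp(x), method="spearman")
        assert r.coefficient == pytest.approx(1.0)

    def test_pearson_equals_spearman_on_rank_linear_data(self, rng):
        x = rng.permutation(np.arange(30, dtype=float))
        y = 3.0 * x - 7.0
        rp = correlate(x, y, method="pearson")
        rs = correlate(x, y, method="spearman")
        assert rp.coefficient == pytest.approx(rs.coefficient)

    def test_null_p_values_uniform(self, rng):
        n_rep, n = 400, 30
        pvals = np.array([
            correlate(rng.standard_normal(n), rng.standard_normal(n),
                      method="spearman").p_value
            for _ in range(n_rep)
        ])
        rate = np.mean(pvals < 0.05)
        assert 0.02 <= rate <= 0.09
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(AssociationError):
            correlate(np.ones(10), rng.standard_normal(10))


class TestSummary:
    def test_hand_computed_mean_and_sd(self):
        rp, na, tg = make_tables(n=2)
        tg["RMT"] = [40.0, 50.0]
        table = assemble_features(rp, na, tg)
        _, targets = summarize_cohort(table)
        assert targets.loc["RMT", "mean"] == pytest.approx(45.0)
        assert targets.loc["RMT", "sd"] == pytest.approx(7.071, abs=1e-3)

    def test_constant_metric_zero_sd(self):
        rp, na, tg = make_tables(n=4)
        rp["power_alpha2"] = 1.5
        table = assemble_features(rp, na, tg)
        metrics, _ = summarize_cohort(table)
        assert metrics.loc["power", ("alpha2", "sd")] == 0.0
        assert metrics.loc["power", ("alpha2", "mean")] == pytest.approx(1.5)

    def test_layout_rows_are_metric_families(self):
        rp, na, tg = make_tables(n=3)
        metrics, _ = summarize_cohort(assemble_features(rp, na, tg))
        assert list(metrics.index) == [
            "power", "cc_global", "eff_global", "cc_nodal_roi",
            "eff_nodal_roi",
        ]
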