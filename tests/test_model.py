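import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from ctra_wellbeing.model import (
    contrast_test,
    fit_repeated_measures,
    omnibus_f,
    percent_difference_effect,
    vif,
    wald_t,
)
from tests.conftest import make_hcs_data


def dense_hcs_oracle(Y, X, n_starts=3):
    """Brute-force ML: optimize the full dense multivariate-normal likelihood
    over (gene intercepts, slopes, log SDs, transformed rho) with a generic
    quasi-Newton optimizer and numeric gradients."""
    n, G = Y.shape
    p = X.shape[1]
    lo = -1.0 / (G - 1) + 1e-6

    def nll(theta):
        mu = theta[:G]
        beta = theta[G : G + p]
        sig = np.exp(theta[G + p : G + p + G])
        rho = lo + (1 - 1e-6 - lo) / (1.0 + np.exp(-theta[-1]))
        R = np.full((G, G), rho)
        np.fill_diagonal(R, 1.0)
        Sigma = R * np.outer(sig, sig)
        resid = Y - mu - (X @ beta)[:, None]
        try:
            return -stats.multivariate_normal(np.zeros(G), Sigma).logpdf(resid).sum()
        except (np.linalg.LinAlgError, ValueError):
            return 1e10

    best = None
    for s in range(n_starts):
        rng = np.random.default_rng(s)
        x0 = np.concatenate([Y.mean(0), np.zeros(p), np.log(Y.std(0, ddof=1)), [0.0]])
        if s:
            x0 = x0 + 0.05 * rng.standard_normal(len(x0))
        r = optimize.minimize(nll, x0, method="BFGS", options={"maxiter": 5000, "gtol": 1e-10})
        if best is None or r.fun < best.fun:
            best = r
    return -best.fun, best.x[G : G + p]


def dense_un_oracle(Y, X):
    """Brute-force ML with an unstructured covariance via its Cholesky factor."""
    n, G = Y.shape
    p = X.shape[1]
    tril = np.tril_indices(G)

    def nll(theta):
        mu = theta[:G]
        beta = theta[G : G + p]
        L = np.zeros((G, G))
        L[tril] = theta[G + p :]
        L[np.diag_indices(G)] = np.exp(np.diag(L))
        Sigma = L @ L.T
        resid = Y - mu - (X @ beta)[:, None]
        try:
            return -stats.multivariate_normal(np.zeros(G), Sigma).logpdf(resid).sum()
        except (np.linalg.LinAlgError, ValueError):
            return 1e10

    S0 = np.cov(Y.T, ddof=0) + 1e-6 * np.eye(G)
    L0 = np.linalg.cholesky(S0)
    start = L0.copy()
    start[np.diag_indices(G)] = np.log(np.diag(L0))
    x0 = np.concatenate([Y.mean(0), np.zeros(p), start[tril]])
    r = optimize.minimize(nll, x0, method="BFGS", options={"maxiter": 10000, "gtol": 1e-10})
    return -r.fun, r.x[G : G + p]


class TestOracleEquivalence:
    def test_hcs_matches_dense_likelihood(self):
        rng = np.random.default_rng(21)
        Y, X, _ = make_hcs_data(rng, n=30, G=4, p=2, beta=np.array([-0.5, 0.2]),
                                sigma=np.array([0.8, 1.2, 1.0, 0.6]), rho=0.4,
                                mu=np.array([1.0, 2.0, 0.5, -1.0]))
        fit = fit_repeated_measures(Y, X, structure="hcs")
        ll_oracle, b_oracle = dense_hcs_oracle(Y.to_numpy(), X.to_numpy())
        assert fit.loglik == pytest.approx(ll_oracle, abs=1e-5)
        assert np.abs(fit.params["b"].to_numpy() - b_oracle).max() < 1e-5

    def test_un_matches_dense_likelihood(self):
        rng = np.random.default_rng(22)
        Y, X, _ = make_hcs_data(rng, n=40, G=3, p=2, beta=np.array([0.3, -0.4]),
                                sigma=np.array([1.0, 0.7, 1.3]), rho=0.3)
        fit = fit_repeated_measures(Y, X, structure="un")
        ll_oracle, b_oracle = dense_un_oracle(Y.to_numpy(), X.to_numpy())
        assert fit.loglik == pytest.approx(ll_oracle, abs=1e-5)
        assert np.abs(fit.params["b"].to_numpy() - b_oracle).max() < 1e-5


class TestReductions:
    def test_single_gene_reduces_to_regression(self):
        rng = np.random.default_rng(23)
        n = 50
        X = pd.DataFrame({"x1": rng.standard_normal(n), "x2": rng.standard_normal(n)})
        y = 1.0 - 0.7 * X["x1"] + 0.3 * X["x2"] + rng.standard_normal(n)
        fit = fit_repeated_measures(pd.DataFrame({"g": y}), X, structure="hcs")
        A = np.column_stack([np.ones(n), X.to_numpy()])
        coef, *_ = np.linalg.lstsq(A, y.to_numpy(), rcond=None)
        resid = y.to_numpy() - A @ coef
        sigma2_ml = (resid**2).sum() / n
        cov_ml = sigma2_ml * np.linalg.inv(A.T @ A)
        assert np.allclose(fit.params["b"], coef[1:], atol=1e-7)
        assert np.allclose(fit.params["se"], np.sqrt(np.diag(cov_ml))[1:], atol=1e-6)

    def test_cs_balanced_equals_composite_ols(self):
        rng = np.random.default_rng(24)
        G, n = 6, 40
        Y, X, _ = make_hcs_data(rng, n=n, G=G, p=2, beta=np.array([-0.5, 0.1]),
                                sigma=np.ones(G), rho=0.35)
        fit = fit_repeated_measures(Y, X, structure="cs")
        composite = Y.mean(axis=1)
        A = np.column_stack([np.ones(n), X.to_numpy()])
        coef, *_ = np.linalg.lstsq(A, composite.to_numpy(), rcond=None)
        assert np.abs(fit.params["b"].to_numpy() - coef[1:]).max() < 1e-10

    def test_cs_matches_statsmodels_random_intercept(self):
        smf = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        rng = np.random.default_rng(25)
        G, n = 5, 60
        Y, X, _ = make_hcs_data(rng, n=n, G=G, p=1, beta=np.array([-0.4]),
                                sigma=np.ones(G), rho=0.4)
        fit = fit_repeated_measures(Y, X, structure="cs")
        long = Y.stack().rename("y").reset_index()
        long.columns = ["subject", "gene", "y"]
        long["x0"] = X["x0"].to_numpy()[long["subject"].to_numpy()]
        import statsmodels.formula.api as smf_api

        md = smf_api.mixedlm("y ~ C(gene) + x0", long, groups=long["subject"])
        sm_fit = md.fit(reml=False)
        assert fit.params.at["x0", "b"] == pytest.approx(sm_fit.params["x0"], abs=1e-4)
        assert fit.params.at["x0", "se"] == pytest.approx(sm_fit.bse["x0"], abs=1e-3)


class TestDfBookkeeping:
    @pytest.mark.parametrize(
        "n,p,expected_df",
        [
            (122, 17, 104),  # 2-d well-being + 7 demographic + 8 markers
            (122, 18, 103),  # 3-d representation
            (122, 16, 105),  # 1-d / categorical representation
            (198, 18, 179),  # pooled sample with study indicator
            (107, 18, 88),   # generalization, one scale at a time
            (107, 23, 83),   # generalization, 6 mutually adjusted scales
        ],
    )
    def test_between_within_df(self, n, p, expected_df):
        rng = np.random.default_rng(n + p)
        Y, X, _ = make_hcs_data(rng, n=n, G=3, p=p, beta=np.zeros(p),
                                sigma=np.full(3, 0.8), rho=0.3)
        fit = fit_repeated_measures(Y, X, structure="hcs", n_starts=1)
        assert int(fit.params["df"].iloc[0]) == expected_df
        t, df, _ = wald_t(fit, "x0")
        assert df == expected_df
        F, (df1, df2), _ = omnibus_f(fit, ["x0", "x1"])
        assert (df1, df2) == (2, expected_df)
        _, dfc, _ = contrast_test(fit, "x0", "x1")
        assert dfc == expected_df


@pytest.fixture(scope="module")
def fit():
    rng = np.random.default_rng(31)
    Y, X, _ = make_hcs_data(rng, n=60, G=4, p=3, beta=np.array([-0.5, 0.0, 0.2]),
                            sigma=np.array([0.8, 1.0, 1.2, 0.9]), rho=0.4)
    return fit_repeated_measures(Y, X, structure="hcs")


class TestWaldMachinery:

    def test_single_term_f_equals_t_squared(self, fit):
        t, _, _ = wald_t(fit, "x0")
        F, _, _ = omnibus_f(fit, ["x0"])
        assert F == pytest.approx(t**2, abs=1e-10)

    def test_self_contrast_is_zero(self, fit):
        t, _, p = contrast_test(fit, "x1", "x1")
        assert t == 0.0 and p == 1.0

    def test_unknown_term_rejected(self, fit):
        with pytest.raises(KeyError):
            wald_t(fit, "nope")
        with pytest.raises(KeyError):
            omnibus_f(fit, ["x0", "nope"])


class TestDiagnostics:
    def test_orthogonal_predictors_give_unit_vif(self):
        X = pd.DataFrame({"a": [1.0, -1.0, 1.0, -1.0], "b": [1.0, 1.0, -1.0, -1.0]})
        assert np.allclose(vif(X), 1.0)

    def test_correlated_pair_closed_form(self):
        rng = np.random.default_rng(41)
        n = 20000
        a = rng.standard_normal(n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        v = vif(pd.DataFrame({"a": a, "b": b}), term="a")
        assert v == pytest.approx(1.0 / (1.0 - 0.81), rel=0.02)

    def test_collinearity_threshold(self):
        rng = np.random.default_rng(42)
        a = rng.standard_normal(500)
        near = a + 0.05 * rng.standard_normal(500)
        mild = 0.5 * a + rng.standard_normal(500)
        vifs = vif(pd.DataFrame({"a": a, "near": near, "mild": mild}))
        assert vifs["near"] > 10
        assert vifs["mild"] < 10

    @pytest.mark.parametrize("b,expected", [(0.0, 0.0), (0.25, 100.0), (-0.25, -50.0)])
    def test_percent_difference_effect(self, b, expected):
        assert percent_difference_effect(b) == pytest.approx(expected, abs=1e-12)


class TestGuards:
    def test_constant_predictor_rejected(self):
        rng = np.random.default_rng(51)
        Y, X, _ = make_hcs_data(rng, n=20, G=3, p=2, beta=np.zeros(2),
                                sigma=np.ones(3), rho=0.2)
        X["const"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_repeated_measures(Y, X)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(52)
        Y, X, _ = make_hcs_data(rng, n=20, G=3, p=2, beta=np.zeros(2),
                                sigma=np.ones(3), rho=0.2)
        X["dup"] = 2.0 * X["x0"]
        with pytest.raises(ValueError, match="rank"):
            fit_repeated_measures(Y, X)

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(53)
        Y, X, _ = make_hcs_data(rng, n=4, G=3, p=2, beta=np.zeros(2),
                                sigma=np.ones(3), rho=0.2)
        with pytest.raises(ValueError, match="n_subjects"):
            fit_repeated_measures(Y, X)
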