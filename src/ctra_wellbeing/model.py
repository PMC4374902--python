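"""Pooled repeated-measures association model for CTRA gene expression.

The CTRA indicator genes are treated as repeated measures on each subject:
for subject ``i`` and gene ``g``,

    y_ig = mu_g + x_i' beta + e_i,   e_i ~ N(0, Sigma),

with gene-specific fixed intercepts ``mu_g``, a common subject-level slope
vector ``beta`` (the average association of the predictors with the
sign-adjusted CTRA profile), and a structured within-subject residual
covariance:

* ``hcs`` — heterogeneous compound symmetry: Sigma_gh = rho * s_g * s_h for
  g != h, s_g^2 on the diagonal (gene-specific SDs, one common correlation);
* ``cs``  — compound symmetry (one SD, one correlation);
* ``un``  — unstructured (full G x G matrix, iterated GLS with optional
  ridge stabilization when G approaches the subject count).

Estimation is maximum likelihood: fixed effects are profiled out by
generalized least squares inside an ascent loop over the covariance
parameters (log SDs and a transformed correlation, quasi-Newton with
analytic gradients, multiple seeded starts).  Inference on subject-level
terms uses the between-within denominator-df convention
``df = n_subjects - #subject-level predictors - 1``, which reproduces the
printed df of the source tables exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

Structure = Literal["hcs", "cs", "un"]


@dataclass(frozen=True)
class CtraModelFit:
    """Fixed-effect estimates and covariance parameters from the pooled model."""

    params: pd.DataFrame  # index: term; columns: b, se, t, df, p, vif
    gene_intercepts: pd.Series
    structure: Structure
    sigma: pd.Series  # per-gene residual SD (hcs/un diag; cs constant)
    rho: float | None  # common correlation (hcs/cs), None for un
    sigma_matrix: pd.DataFrame  # implied / estimated G x G residual covariance
    coef_cov: pd.DataFrame  # ML covariance of the subject-level slopes
    loglik: float
    n_subjects: int
    n_genes: int
    ddf: int
    converged: bool
    n_iter: int

    def term(self, name: str) -> pd.Series:
        if name not in self.params.index:
            raise KeyError(f"term {name!r} not in model")
        return self.params.loc[name]


def _hcs_bounds(G: int) -> tuple[float, float]:
    lo = -1.0 / (G - 1) + 1e-6 if G > 1 else -0.999999
    return lo, 1.0 - 1e-6


def _rho_from_z(z: float, lo: float, hi: float) -> float:
    return lo + (hi - lo) * special.expit(z)


def _z_from_rho(rho: float, lo: float, hi: float) -> float:
    frac = np.clip((rho - lo) / (hi - lo), 1e-9, 1 - 1e-9)
    return float(special.logit(frac))


def _hcs_objective(theta, S, G, homogeneous, lo, hi):
    """log|Sigma| + tr(S Sigma^-1) for Sigma = D R(rho) D, with gradient."""
    if homogeneous:
        u = np.full(G, theta[0])
    else:
        u = theta[:G]
    z = theta[-1]
    rho = _rho_from_z(z, lo, hi)
    sig = np.exp(u)
    W = S / np.outer(sig, sig)
    trW = np.trace(W)
    q = W.sum(axis=1)  # row sums
    s1 = q.sum()
    alpha = rho / (1.0 + (G - 1) * rho)
    one_m = 1.0 - rho
    logdet_R = (G - 1) * np.log(one_m) + np.log1p((G - 1) * rho)
    f = 2.0 * u.sum() + logdet_R + (trW - alpha * s1) / one_m
    # gradient wrt u_g
    gu = 2.0 + (-2.0 * np.diag(W) + 2.0 * alpha * q) / one_m
    # gradient wrt rho
    dalpha = 1.0 / (1.0 + (G - 1) * rho) ** 2
    dT = (trW - alpha * s1) / one_m**2 - dalpha * s1 / one_m
    drho = -(G - 1) / one_m + (G - 1) / (1.0 + (G - 1) * rho) + dT
    dz = drho * (hi - lo) * special.expit(z) * (1.0 - special.expit(z))
    if homogeneous:
        grad = np.array([gu.sum(), dz])
    else:
        grad = np.concatenate([gu, [dz]])
    return f, grad


def _hcs_sigma(sig: np.ndarray, rho: float) -> np.ndarray:
    G = len(sig)
    R = np.full((G, G), rho)
    np.fill_diagonal(R, 1.0)
    return R * np.outer(sig, sig)


def _gls(Y, X, A):
    """Profile GLS for gene intercepts + common slopes given A = Sigma^-1.

    Exploits the balanced layout: the whitened normal equations reduce to
    closed-form blocks in A, A1, 1'A1 and the subject-level design moments.
    """
    n, G = Y.shape
    p = X.shape[1]
    a = A.sum(axis=1)
    c = a.sum()
    Ysum = Y.sum(axis=0)
    M = np.empty((G + p, G + p))
    M[:G, :G] = n * A
    rhs = np.empty(G + p)
    rhs[:G] = A @ Ysum
    if p:
        Sx = X.sum(axis=0)
        M[:G, G:] = np.outer(a, Sx)
        M[G:, :G] = M[:G, G:].T
        M[G:, G:] = c * (X.T @ X)
        rhs[G:] = X.T @ (Y @ a)
    theta = np.linalg.solve(M, rhs)
    return theta[:G], theta[G:], M


def fit_repeated_measures(
    Y: pd.DataFrame,
    X: pd.DataFrame | None,
    structure: Structure = "hcs",
    n_starts: int = 3,
    max_iter: int = 500,
    tol: float = 1e-9,
    ridge: float = 0.0,
    seed: int = 0,
) -> CtraModelFit:
    """ML fit of the repeated-measures model on wide data.

    Parameters
    ----------
    Y
        Subjects x genes response matrix (sign-adjusted, standardized or
        centered log2), complete (balanced panel).
    X
        Subjects x predictors design of subject-level terms, without an
        intercept column (the gene intercepts absorb it).  ``None`` fits the
        intercept-only model.
    structure
        Within-subject residual covariance structure.
    ridge
        For ``un`` only: fraction of the mean residual variance added to the
        diagonal each update, stabilizing estimation when G approaches n.
    """
    Y = Y.dropna(axis=0, how="any")
    genes = list(Y.columns)
    if X is None:
        X = pd.DataFrame(index=Y.index)
    X = X.loc[Y.index]
    if X.isna().any().any():
        raise ValueError("predictor design contains missing values")
    n, G = Y.shape
    p = X.shape[1]
    if n <= p + 2:
        raise ValueError(f"need n_subjects > predictors + 2 (n={n}, p={p})")
    if p:
        const = X.std(axis=0, ddof=0) == 0
        if const.any():
            raise ValueError(
                f"constant predictor columns (gene intercepts absorb the "
                f"intercept): {list(X.columns[const])}"
            )
        full = np.column_stack([np.ones(n), X.to_numpy(float)])
        if np.linalg.matrix_rank(full) < p + 1:
            raise ValueError("predictor design is rank-deficient")
    Yv = Y.to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)

    def loglik_from(A, logdet, S):
        return -0.5 * n * (G * np.log(2 * np.pi) + logdet + np.trace(S @ A))

    # OLS start
    mu, beta, _ = _gls(Yv, Xv, np.eye(G))
    E = Yv - mu - (Xv @ beta)[:, None] if p else Yv - mu
    S = E.T @ E / n

    if structure == "un":
        Sigma = S.copy()
        ll_old, it, converged = -np.inf, 0, False
        for it in range(1, max_iter + 1):
            if ridge > 0:
                Sigma = Sigma + ridge * np.mean(np.diag(Sigma)) * np.eye(G)
            A = np.linalg.inv(Sigma)
            mu, beta, M = _gls(Yv, Xv, A)
            E = Yv - mu - (Xv @ beta)[:, None] if p else Yv - mu
            S = E.T @ E / n
            sign, logdet = np.linalg.slogdet(Sigma)
            ll = loglik_from(A, logdet, S)
            if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
                converged = True
                break
            ll_old = ll
            Sigma = S.copy()
        sig = np.sqrt(np.diag(Sigma))
        rho_hat = None
        best_ll, best_iter = ll, it
    else:
        homogeneous = structure == "cs"
        lo, hi = _hcs_bounds(G)
        rng = np.random.default_rng(seed)
        start_rhos = [0.0, 0.3, 0.6][:n_starts]
        while len(start_rhos) < n_starts:
            start_rhos.append(float(rng.uniform(lo * 0.5, 0.9)))
        best = None
        for rho0 in start_rhos:
            mu_c, beta_c = mu.copy(), beta.copy()
            S_c = S.copy()
            d0 = np.diag(S_c).mean() if homogeneous else np.diag(S_c)
            u0 = 0.5 * np.log(np.atleast_1d(d0))
            theta = np.concatenate([u0, [_z_from_rho(rho0, lo, hi)]])
            ll_old, converged = -np.inf, False
            for it in range(1, max_iter + 1):
                res = optimize.minimize(
                    _hcs_objective,
                    theta,
                    args=(S_c, G, homogeneous, lo, hi),
                    jac=True,
                    method="L-BFGS-B",
                    options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12},
                )
                theta = res.x
                u = np.full(G, theta[0]) if homogeneous else theta[:G]
                rho_c = _rho_from_z(theta[-1], lo, hi)
                sig_c = np.exp(u)
                Sigma_c = _hcs_sigma(sig_c, rho_c) if G > 1 else np.array([[sig_c[0] ** 2]])
                A = np.linalg.inv(Sigma_c)
                mu_c, beta_c, M = _gls(Yv, Xv, A)
                E = Yv - mu_c - (Xv @ beta_c)[:, None] if p else Yv - mu_c
                S_c = E.T @ E / n
                sign, logdet = np.linalg.slogdet(Sigma_c)
                ll = loglik_from(A, logdet, S_c)
                if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
                    converged = True
                    break
                ll_old = ll
            cand = (ll, converged, it, mu_c, beta_c, sig_c, rho_c, Sigma_c, M)
            if best is None or cand[0] > best[0]:
                best = cand
        best_ll, converged, best_iter, mu, beta, sig, rho_hat, Sigma, M = best
        A = np.linalg.inv(Sigma)

    # final GLS quantities and coefficient covariance
    mu, beta, M = _gls(Yv, Xv, np.linalg.inv(Sigma))
    V = np.linalg.inv(M)
    Vb = V[G:, G:]
    ddf = n - p - 1
    b = beta
    se = np.sqrt(np.diag(Vb)) if p else np.array([])
    with np.errstate(invalid="ignore"):
        tvals = b / se if p else np.array([])
    pvals = 2.0 * stats.t.sf(np.abs(tvals), ddf) if p else np.array([])
    vifs = vif(X) if p else pd.Series(dtype=float)
    params = pd.DataFrame(
        {"b": b, "se": se, "t": tvals, "df": ddf, "p": pvals, "vif": vifs.reindex(X.columns)},
        index=X.columns,
    )
    sigma_series = pd.Series(np.sqrt(np.diag(Sigma)), index=genes, name="sigma")
    return CtraModelFit(
        params=params,
        gene_intercepts=pd.Series(mu, index=genes, name="intercept"),
        structure=structure,
        sigma=sigma_series,
        rho=None if structure == "un" else float(rho_hat),
        sigma_matrix=pd.DataFrame(Sigma, index=genes, columns=genes),
        coef_cov=pd.DataFrame(Vb, index=X.columns, columns=X.columns),
        loglik=float(best_ll),
        n_subjects=n,
        n_genes=G,
        ddf=int(ddf),
        converged=bool(converged),
        n_iter=int(best_iter),
    )


def fit_ctra_model(
    long: pd.DataFrame,
    predictors: Sequence[str],
    structure: Structure = "hcs",
    standardize: Sequence[str] = (),
    **kwargs,
) -> CtraModelFit:
    """Fit from the long-format assembly produced by ``to_long_format``.

    ``standardize`` lists predictor columns to z-score on the analyzed sample
    (the convention for reporting standardized association coefficients).
    """
    from .expression import long_to_wide

    Y = long_to_wide(long)
    X = long.drop_duplicates("subject_id").set_index("subject_id")[list(predictors)]
    X = X.loc[Y.index].astype(float)
    for col in standardize:
        sd = X[col].std(ddof=1)
        if sd <= 0:
            raise ValueError(f"cannot standardize constant predictor {col!r}")
        X[col] = (X[col] - X[col].mean()) / sd
    return fit_repeated_measures(Y, X, structure=structure, **kwargs)


def wald_t(fit: CtraModelFit, term: str) -> tuple[float, int, float]:
    """Wald t-test of one subject-level coefficient (between-within df)."""
    row = fit.term(term)
    return float(row["t"]), int(row["df"]), float(row["p"])


def omnibus_f(fit: CtraModelFit, term_group: Sequence[str]) -> tuple[float, tuple[int, int], float]:
    """Wald F on the joint null that all coefficients in the group are zero."""
    terms = list(term_group)
    if not terms:
        raise ValueError("empty term group")
    missing = [t for t in terms if t not in fit.params.index]
    if missing:
        raise KeyError(f"terms not in model: {missing}")
    b = fit.params.loc[terms, "b"].to_numpy()
    Vc = fit.coef_cov.loc[terms, terms].to_numpy()
    q = len(terms)
    F = float(b @ np.linalg.solve(Vc, b) / q)
    df2 = fit.ddf
    return F, (q, df2), float(stats.f.sf(F, q, df2))


def contrast_test(fit: CtraModelFit, term_a: str, term_b: str) -> tuple[float, int, float]:
    """Test b_a - b_b = 0 (e.g. eudaimonic vs hedonic association magnitude)."""
    for t in (term_a, term_b):
        fit.term(t)
    diff = fit.params.at[term_a, "b"] - fit.params.at[term_b, "b"]
    var = (
        fit.coef_cov.at[term_a, term_a]
        + fit.coef_cov.at[term_b, term_b]
        - 2.0 * fit.coef_cov.at[term_a, term_b]
    )
    if var <= 0:
        return 0.0, fit.ddf, 1.0
    tval = float(diff / np.sqrt(var))
    return tval, fit.ddf, float(2.0 * stats.t.sf(abs(tval), fit.ddf))


def vif(design: pd.DataFrame, term: str | None = None) -> pd.Series | float:
    """Variance inflation factor: 1 / (1 - R^2) of each regressor on the rest.

    Values above 10 indicate problematic multicollinearity.
    """
    X = design.astype(float)
    if X.shape[1] < 2:
        out = pd.Series(1.0, index=X.columns)
        return out if term is None else float(out[term])
    cols = list(X.columns)
    out = {}
    for col in cols:
        others = [c for c in cols if c != col]
        A = np.column_stack([np.ones(len(X)), X[others].to_numpy()])
        y = X[col].to_numpy()
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = ((y - y.mean()) ** 2).sum()
        if ss_tot == 0:
            raise ValueError(f"VIF undefined for constant column {col!r}")
        r2 = 1.0 - (resid**2).sum() / ss_tot
        out[col] = 1.0 / max(1.0 - r2, 1e-12)
    series = pd.Series(out)[cols]
    return series if term is None else float(series[term])


def percent_difference_effect(b_unstd_log2_per_sd: float) -> float:
    """Percent difference in transcript abundance across a 4-SD predictor span.

    A log2-metric slope ``b`` per predictor SD implies a fold change of
    ``2**(4b)`` between -2 SD and +2 SD, i.e. ``100 * (2**(4b) - 1)`` percent.
    """
    return float(100.0 * (2.0 ** (4.0 * b_unstd_log2_per_sd) - 1.0))
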