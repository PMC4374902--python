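"""Maximum-likelihood confirmatory factor analysis with nested chi-square tests.

Congeneric CFA: every item loads on exactly one factor, factor variances are
fixed to 1 for identification, factor correlations are free, uniquenesses are
free and positive.  The model-implied covariance is ``Sigma = L Phi L' + Psi``
and the ML discrepancy minimized is

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

with test statistic ``T = (n - 1) * F_ML`` referred to a chi-square on
``p(p+1)/2 - #free parameters`` degrees of freedom.  Nested models (a factor
correlation fixed at 1, i.e. two factors merged) are compared by the
chi-square difference test.

Optimization is quasi-Newton (L-BFGS-B) with an analytic gradient, multistart
from seeded perturbed starting values, and a gradient-norm convergence check.
Factor correlations are free (unconstrained) parameters, as in standard ML
CFA software: improper solutions (|phi| > 1) are permitted so that nested
likelihood-ratio tests keep their chi-square reference distribution when the
restriction lies on the correlation boundary; only positive-definiteness of
the implied covariance is enforced during optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

GRAD_TOL = 1e-8  # target gradient-infinity-norm at the solution
_HEYWOOD_FRAC = 5e-3  # uniqueness below this fraction of the item variance


@dataclass(frozen=True)
class CfaModelSpec:
    """Congeneric factor pattern: item -> factor, all factor correlations free."""

    loading_pattern: Mapping[str, str]

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.loading_pattern)

    @property
    def factors(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for f in self.loading_pattern.values():
            seen.setdefault(f)
        return tuple(seen)

    @property
    def n_free_parameters(self) -> int:
        p, k = len(self.items), len(self.factors)
        return 2 * p + k * (k - 1) // 2

    def model_df(self) -> int:
        p = len(self.items)
        return p * (p + 1) // 2 - self.n_free_parameters


@dataclass(frozen=True)
class CfaFit:
    spec: CfaModelSpec
    loadings: pd.Series
    uniquenesses: pd.Series
    factor_corr: pd.DataFrame
    f_ml: float
    statistic: float  # T = (n - 1) * F_ML
    df: int
    loglik: float
    n: int
    converged: bool
    heywood: bool
    grad_norm: float


def _unpack(theta: np.ndarray, p: int, k: int):
    lam = theta[:p]
    psi = np.exp(theta[p : 2 * p])
    Phi = np.eye(k)
    iu = np.triu_indices(k, 1)
    Phi[iu] = theta[2 * p :]
    Phi[(iu[1], iu[0])] = theta[2 * p :]
    return lam, psi, Phi


def _objective_and_grad(theta, S, pattern_idx, p, k):
    lam, psi, Phi = _unpack(theta, p, k)
    L = np.zeros((p, k))
    L[np.arange(p), pattern_idx] = lam
    Sigma = L @ Phi @ L.T + np.diag(psi)
    try:
        cho = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        # infeasible (indefinite Sigma): smooth finite penalty on the minimum
        # eigenvalue so the line search can interpolate back to feasibility
        w, V = np.linalg.eigh(Sigma)
        v = V[:, 0]
        f = 1e6 * (1.0 - w[0])
        G = -1e6 * np.outer(v, v)
        grad = np.zeros_like(theta)
        GLPhi = G @ L @ Phi
        grad[:p] = 2.0 * GLPhi[np.arange(p), pattern_idx]
        grad[p : 2 * p] = np.diag(G) * psi
        if k > 1:
            iu = np.triu_indices(k, 1)
            grad[2 * p :] = 2.0 * (L.T @ G @ L)[iu]
        return f, grad
    logdet = 2.0 * np.log(np.diag(cho)).sum()
    Sinv = np.linalg.inv(Sigma)
    sign_s, logdet_s = np.linalg.slogdet(S)
    f = logdet + np.trace(Sinv @ S) - logdet_s - p
    # dF/dSigma = Sigma^-1 - Sigma^-1 S Sigma^-1
    G = Sinv - Sinv @ S @ Sinv
    GLPhi = G @ L @ Phi
    grad = np.zeros_like(theta)
    grad[:p] = 2.0 * GLPhi[np.arange(p), pattern_idx]
    grad[p : 2 * p] = np.diag(G) * psi
    if k > 1:
        M = L.T @ G @ L  # dF/dPhi; off-diagonal entries appear twice
        iu = np.triu_indices(k, 1)
        grad[2 * p :] = 2.0 * M[iu]
    return f, grad


def fit_cfa_ml(
    spec: CfaModelSpec,
    data: pd.DataFrame | None = None,
    cov: pd.DataFrame | np.ndarray | None = None,
    n: int | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> CfaFit:
    """Fit a congeneric CFA by maximum likelihood.

    Provide either raw ``data`` (subjects x items; the Pearson covariance is
    taken) or a sample covariance ``cov`` with its sample size ``n``.
    """
    items = list(spec.items)
    if data is not None:
        data = data[items].dropna()
        n = len(data)
        S = np.cov(data.to_numpy(dtype=float), rowvar=False, ddof=1)
    else:
        if cov is None or n is None:
            raise ValueError("need either data or (cov, n)")
        S = pd.DataFrame(cov).loc[items, items].to_numpy(dtype=float) if isinstance(
            cov, pd.DataFrame
        ) else np.asarray(cov, dtype=float)
    p, k = len(items), len(spec.factors)
    if n <= spec.n_free_parameters:
        raise ValueError("sample size must exceed the number of free parameters")
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError("sample covariance must be positive definite")
    factor_index = {f: i for i, f in enumerate(spec.factors)}
    pattern_idx = np.array([factor_index[spec.loading_pattern[i]] for i in items])
    diag = np.diag(S)

    rng = np.random.default_rng(seed)
    n_corr = k * (k - 1) // 2
    best = None
    for start in range(n_starts):
        lam0 = np.sqrt(0.5 * diag) * (1.0 + 0.1 * rng.standard_normal(p) * (start > 0))
        psi0 = np.log(0.5 * diag) + 0.1 * rng.standard_normal(p) * (start > 0)
        phi0 = np.full(n_corr, 0.5) + 0.1 * rng.standard_normal(n_corr) * (start > 0)
        theta0 = np.concatenate([lam0, psi0, phi0])
        res = optimize.minimize(
            _objective_and_grad,
            theta0,
            args=(S, pattern_idx, p, k),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    # polish: restarting L-BFGS resets its Hessian approximation, which helps
    # on the flat ridges that arise when a factor correlation sits near 1
    for _ in range(6):
        if np.isfinite(best.fun) and np.max(np.abs(best.jac)) < 1e-6:
            break
        res = optimize.minimize(
            _objective_and_grad,
            best.x,
            args=(S, pattern_idx, p, k),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12},
        )
        if res.fun <= best.fun:
            best = res
        else:
            break
    lam, psi, Phi = _unpack(best.x, p, k)
    # resolve sign indeterminacy: make the mean loading of each factor positive
    for f in range(k):
        mask = pattern_idx == f
        if lam[mask].sum() < 0:
            lam[mask] *= -1.0
            Phi[f, :] *= -1.0
            Phi[:, f] *= -1.0
    f_ml = float(best.fun)
    grad_norm = float(np.max(np.abs(best.jac)))
    # the optimizer's own status flag can report an abnormal line-search exit
    # at a stationary point; the gradient norm is the criterion that matters
    converged = bool(np.isfinite(f_ml)) and grad_norm < 1e-5
    heywood = bool((psi < _HEYWOOD_FRAC * diag).any())
    _, logdet_s = np.linalg.slogdet(S)
    loglik = -0.5 * n * (p * np.log(2 * np.pi) + f_ml + logdet_s + p)
    fit = CfaFit(
        spec=spec,
        loadings=pd.Series(lam, index=items, name="loading"),
        uniquenesses=pd.Series(psi, index=items, name="uniqueness"),
        factor_corr=pd.DataFrame(Phi, index=spec.factors, columns=spec.factors),
        f_ml=f_ml,
        statistic=float((n - 1) * f_ml),
        df=spec.model_df(),
        loglik=float(loglik),
        n=int(n),
        converged=converged,
        heywood=heywood,
        grad_norm=grad_norm,
    )
    if not converged:
        raise ConvergenceWarningError(fit)
    return fit


class ConvergenceWarningError(RuntimeError):
    """Raised when the CFA optimizer fails the gradient-norm check."""

    def __init__(self, fit: CfaFit):
        self.fit = fit
        super().__init__(
            f"CFA did not converge (gradient norm {fit.grad_norm:.2e}); "
            "partial results attached"
        )


def _is_nested(restricted: CfaModelSpec, general: CfaModelSpec) -> bool:
    """Restricted = general with some factors merged (correlation fixed at 1)."""
    if set(restricted.items) != set(general.items):
        return False
    merge_map: dict[str, str] = {}
    for item in general.items:
        gf = general.loading_pattern[item]
        rf = restricted.loading_pattern[item]
        if merge_map.setdefault(gf, rf) != rf:
            return False
    return True


def nested_chisq_test(fit_restricted: CfaFit, fit_general: CfaFit) -> tuple[float, int, float]:
    """Chi-square difference test between nested CFA fits on the same sample."""
    if fit_restricted.n != fit_general.n:
        raise ValueError("fits compare different samples")
    if not _is_nested(fit_restricted.spec, fit_general.spec):
        raise ValueError("models are not nested (restricted must merge general's factors)")
    delta_df = fit_restricted.df - fit_general.df
    delta_x2 = fit_restricted.statistic - fit_general.statistic
    if delta_x2 < -1e-6:
        raise ValueError(
            f"restricted model fits better than general (dX2 = {delta_x2:.3g}); "
            "optimization failure"
        )
    delta_x2 = max(delta_x2, 0.0)
    if delta_df == 0:
        return delta_x2, 0, 1.0
    return float(delta_x2), int(delta_df), float(stats.chi2.sf(delta_x2, delta_df))


def mhcsf_cfa_specs() -> dict[str, CfaModelSpec]:
    """The three MHC-SF factor structures compared in the psychometric analyses."""
    from .psychometrics import MHCSF_KEYES_MAP

    one = CfaModelSpec({i: "wellbeing" for i in MHCSF_KEYES_MAP})
    two = CfaModelSpec(
        {i: ("hedonic" if s == "hedonic" else "eudaimonic") for i, s in MHCSF_KEYES_MAP.items()}
    )
    three = CfaModelSpec(dict(MHCSF_KEYES_MAP))
    return {"1-factor": one, "2-factor": two, "3-factor": three}
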