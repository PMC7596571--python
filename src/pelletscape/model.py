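"""Maximum-likelihood estimation of the random-effects spatial-error panel
model, its fixed-effects counterpart, and the Hausman specification test.

Model.  For period t the N-vector of responses is

    y_t = alpha + Z_t beta + u_t,      u_t = (I - rho W)^{-1} eps_t,

with composite errors eps_{i,t} = mu_i + nu_{i,t}: a landscape random effect
mu_i ~ N(0, sigma2_mu) shared across periods plus an idiosyncratic
innovation nu_{i,t} ~ N(0, sigma2_nu).  W is the row-normalized truncated
inverse-distance weight matrix and rho in (-1, 1) the spatial autoregressive
parameter.  Writing B = I - rho W, the NT disturbance covariance is

    Omega = (sigma2_mu J_T + sigma2_nu I_T) (x) (B^{-1} B^{-T}),

where J_T is the all-ones T×T matrix and (x) the Kronecker product.

Estimation concentrates the likelihood: for fixed (rho, theta) with
theta = sigma2_mu / sigma2_nu, spatially filtering each period by B and
quasi-demeaning across time with c = 1 - (1 + T*theta)^{-1/2} turns GLS into
OLS, giving beta and sigma2_nu in closed form; a bounded quasi-Newton search
with deterministic multi-starts handles the remaining two parameters.

Observation stacking is period-major throughout: index t*N + i.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats
from scipy.linalg import pinvh

logger = logging.getLogger(__name__)

RHO_BOUND = 0.999
THETA_MAX = 1.0e6
DEFAULT_RHO_STARTS = (-0.5, 0.0, 0.5)
OPT_TOL = 1e-10


# ---------------------------------------------------------------------------
# likelihood

def _as_tn(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be a (T, N) array")
    return Y


def _design_tensor(Z: np.ndarray, T: int, N: int) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 2:  # (NT, K) period-major
        Z = Z.reshape(T, N, -1)
    if Z.shape[:2] != (T, N):
        raise ValueError("design shape inconsistent with Y")
    return Z


def re_loglik(
    beta: np.ndarray,
    rho: float,
    sigma2_mu: float,
    sigma2_nu: float,
    Y: np.ndarray,
    Z: np.ndarray,
    W: np.ndarray,
) -> float:
    """Exact Gaussian log-likelihood of the model at the given parameters.

    ``beta`` includes the intercept as its first entry and is aligned with
    the columns of ``Z`` (which must *not* contain an intercept column).
    Evaluates the log-determinant and quadratic form through the Kronecker
    eigenstructure rather than by forming the NT×NT covariance.
    """
    Y = _as_tn(Y)
    T, N = Y.shape
    Z = _design_tensor(Z, T, N)
    if sigma2_nu <= 0:
        raise ValueError("sigma2_nu must be positive")
    if sigma2_mu < 0:
        raise ValueError("sigma2_mu must be non-negative")
    if abs(rho) >= 1.0:
        raise ValueError("|rho| must be < 1")
    beta = np.asarray(beta, dtype=float)
    B = np.eye(N) - rho * np.asarray(W, dtype=float)
    sign, logdetB = np.linalg.slogdet(B)
    if sign <= 0:
        raise ValueError("I - rho*W is singular or negative-definite at this rho")

    resid = Y - beta[0] - np.einsum("tnk,k->tn", Z, beta[1:])
    E = resid @ B.T  # spatially filtered residuals, period by period
    lam1 = sigma2_nu + T * sigma2_mu
    ssq = float((E * E).sum())
    s_sum = E.sum(axis=0)
    qf = (ssq - (sigma2_mu / lam1) * float(s_sum @ s_sum)) / sigma2_nu
    logdet_omega = N * ((T - 1) * math.log(sigma2_nu) + math.log(lam1)) - 2.0 * T * logdetB
    return -0.5 * (N * T * math.log(2.0 * math.pi) + logdet_omega + qf)


def _filtered(
    rho: float, Y: np.ndarray, Z: np.ndarray, W: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Spatially filter response and design by B = I - rho W; also return
    log|B|.  Returns (Y_f (T,N), Z_f (T,N,K+1) with leading intercept)."""
    T, N = Y.shape
    B = np.eye(N) - rho * W
    sign, logdetB = np.linalg.slogdet(B)
    if sign <= 0:
        return None, None, -np.inf
    Yf = Y @ B.T
    ones = np.broadcast_to(B.sum(axis=1), (T, N)).copy()  # filtered intercept
    Zf = np.einsum("ij,tjk->tik", B, Z)
    Zf = np.concatenate([ones[:, :, None], Zf], axis=2)
    return Yf, Zf, logdetB


def concentrated_loglik(
    rho: float,
    theta: float,
    Y: np.ndarray,
    Z: np.ndarray,
    W: np.ndarray,
    return_fit: bool = False,
    reml: bool = False,
):
    """Profile log-likelihood in (rho, theta = sigma2_mu/sigma2_nu), with
    beta and sigma2_nu concentrated out in closed form.

    With ``reml=True`` the restricted (residual) likelihood is profiled
    instead: sigma2_nu concentrates to RSS/(NT-K) and the criterion carries
    the usual -0.5 log|X*'X*| penalty for the estimated mean parameters.
    """
    Y = _as_tn(Y)
    T, N = Y.shape
    Z = _design_tensor(Z, T, N)
    if theta < 0 or abs(rho) >= 1.0:
        return -np.inf if not return_fit else (-np.inf, None)
    Yf, Zf, logdetB = _filtered(rho, Y, Z, np.asarray(W, dtype=float))
    if not np.isfinite(logdetB):
        return -np.inf if not return_fit else (-np.inf, None)
    c = 1.0 - 1.0 / math.sqrt(1.0 + T * theta)
    ys = (Yf - c * Yf.mean(axis=0)).reshape(-1)
    Xs = (Zf - c * Zf.mean(axis=0)).reshape(T * N, -1)
    coef, _, rank, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    if rank < Xs.shape[1]:
        logger.warning("design rank-deficient at rho=%.4f", rho)
    resid = ys - Xs @ coef
    rss = float(resid @ resid)
    NT = N * T
    if rss <= 0:
        return -np.inf if not return_fit else (-np.inf, None)
    if reml:
        K = Xs.shape[1]
        df = NT - K
        sign, logdet_xtx = np.linalg.slogdet(Xs.T @ Xs)
        if sign <= 0:
            return -np.inf if not return_fit else (-np.inf, None)
        ll = (
            -0.5 * df * (math.log(2.0 * math.pi) + 1.0)
            - 0.5 * df * math.log(rss / df)
            - 0.5 * N * math.log(1.0 + T * theta)
            + T * logdetB
            - 0.5 * logdet_xtx
        )
    else:
        ll = (
            -0.5 * NT * (math.log(2.0 * math.pi) + 1.0)
            - 0.5 * NT * math.log(rss / NT)
            - 0.5 * N * math.log(1.0 + T * theta)
            + T * logdetB
        )
    if not return_fit:
        return ll
    return ll, {"coef": coef, "rss": rss, "Xs": Xs, "ys": ys}


# ---------------------------------------------------------------------------
# fitting

@dataclass
class SpatialREFit:
    names: List[str]               # "intercept" first
    params: np.ndarray             # alpha + betas
    rho: float
    sigma2_mu: float               # df-adjusted, theta * sigma2_nu
    sigma2_nu: float               # df-adjusted RSS/(NT - K)
    sigma2_mu_ml: float
    sigma2_nu_ml: float
    theta: float
    loglik: float
    vcov: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: bool
    n_obs: int
    diagnostics: Dict = field(default_factory=dict)

    @property
    def alpha(self) -> float:
        return float(self.params[0])

    @property
    def beta(self) -> np.ndarray:
        return self.params[1:]


@dataclass
class SpatialFEFit:
    names: List[str]               # time-variant covariates only
    params: np.ndarray
    rho: float
    sigma2_nu: float
    loglik: float
    vcov: np.ndarray
    se: np.ndarray
    converged: bool
    n_obs: int
    diagnostics: Dict = field(default_factory=dict)


@dataclass
class HausmanResult:
    statistic: float
    dof: int
    p: float
    decision: str                  # "random" or "fixed"
    used_pseudo_inverse: bool
    shared: List[str]


def fit_spatial_re(
    Y: np.ndarray,
    Z: np.ndarray,
    W: np.ndarray,
    names: Optional[Sequence[str]] = None,
    rho_starts: Sequence[float] = DEFAULT_RHO_STARTS,
    theta_starts: Sequence[float] = (0.1, 1.0),
    fix_rho: Optional[float] = None,
    fix_theta: Optional[float] = None,
    rho_bound: float = RHO_BOUND,
    reml: bool = False,
) -> SpatialREFit:
    """Maximum-likelihood fit of the random-effects spatial-error model.

    ``Y`` is (T, N); ``Z`` is (NT, K) or (T, N, K) without an intercept
    column (one is added).  ``fix_rho`` / ``fix_theta`` pin the spatial
    parameter or the variance ratio, which turns the fit into the matching
    degenerate model (OLS, classical one-way RE, pooled spatial-error).
    ``reml=True`` maximizes the restricted likelihood instead, trading
    plain-ML point estimates for reduced small-sample bias in
    (rho, sigma2_mu, sigma2_nu).
    """
    Y = _as_tn(Y)
    T, N = Y.shape
    Z = _design_tensor(Z, T, N)
    K = Z.shape[2] + 1
    if K >= N * T:
        raise ValueError("more coefficients than observations")
    W = np.asarray(W, dtype=float)

    def negll(x):
        rho = fix_rho if fix_rho is not None else x[0]
        theta = fix_theta if fix_theta is not None else x[-1]
        return -concentrated_loglik(rho, theta, Y, Z, W, reml=reml)

    free_rho = fix_rho is None
    free_theta = fix_theta is None
    best = None
    if free_rho or free_theta:
        starts = []
        for r0 in (rho_starts if free_rho else [0.0]):
            for t0 in (theta_starts if free_theta else [0.0]):
                x0, bounds = [], []
                if free_rho:
                    x0.append(r0)
                    bounds.append((-rho_bound, rho_bound))
                if free_theta:
                    x0.append(t0)
                    bounds.append((0.0, THETA_MAX))
                starts.append((x0, bounds))
        for x0, bounds in starts:
            res = optimize.minimize(
                negll,
                np.asarray(x0),
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": OPT_TOL, "gtol": 1e-9, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        rho_hat = fix_rho if not free_rho else float(best.x[0])
        theta_hat = fix_theta if not free_theta else float(best.x[-1])
        converged = bool(best.success)
        nit = int(best.nit)
    else:
        rho_hat, theta_hat, converged, nit = float(fix_rho), float(fix_theta), True, 0

    ll, fit = concentrated_loglik(rho_hat, theta_hat, Y, Z, W, return_fit=True, reml=reml)
    if fit is None:
        raise RuntimeError("likelihood not finite at the reported optimum")
    coef, rss, Xs = fit["coef"], fit["rss"], fit["Xs"]
    NT = N * T
    s2_ml = rss / NT
    df = NT - K
    s2 = rss / df
    XtX = Xs.T @ Xs
    vcov = s2 * pinvh(XtX)  # PSD pseudo-inverse: robust to near-collinearity
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = coef / se
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    if not converged:
        logger.warning("RE fit did not converge (nit=%d)", nit)
    cov_names = ["intercept"] + (
        list(names) if names is not None else [f"x{i}" for i in range(K - 1)]
    )
    return SpatialREFit(
        names=cov_names,
        params=coef,
        rho=rho_hat,
        sigma2_mu=theta_hat * s2,
        sigma2_nu=s2,
        sigma2_mu_ml=theta_hat * s2_ml,
        sigma2_nu_ml=s2_ml,
        theta=theta_hat,
        loglik=float(ll),
        vcov=vcov,
        se=se,
        z=zval,
        p=pval,
        converged=converged,
        n_obs=NT,
        diagnostics={"nit": nit, "rss": rss, "reml": reml},
    )


def fit_spatial_fe(
    Y: np.ndarray,
    Z: np.ndarray,
    W: np.ndarray,
    names: Optional[Sequence[str]] = None,
    rho_starts: Sequence[float] = DEFAULT_RHO_STARTS,
    rho_bound: float = RHO_BOUND,
    demean_tol: float = 1e-9,
) -> SpatialFEFit:
    """Fixed-effects counterpart: within-demean each landscape over time,
    then fit a pooled spatial-error model on the demeaned data.  Only
    time-variant covariates survive demeaning; pass exactly those."""
    Y = _as_tn(Y)
    T, N = Y.shape
    if T < 2:
        raise ValueError("fixed-effects fit needs T >= 2")
    Z = _design_tensor(Z, T, N)
    W = np.asarray(W, dtype=float)
    Yd = Y - Y.mean(axis=0)
    Zd = Z - Z.mean(axis=0)
    scale = np.abs(Z).reshape(-1, Z.shape[2]).mean(axis=0)
    sd = np.abs(Zd).reshape(-1, Z.shape[2]).max(axis=0)
    dead = sd <= demean_tol * np.maximum(scale, 1.0)
    if dead.all():
        raise ValueError("no time-variant covariates: fixed-effects model unidentified")
    if dead.any():
        which = [i for i, b in enumerate(dead) if b]
        raise ValueError(f"time-invariant columns passed to FE fit: {which}")
    K = Z.shape[2]
    NT = N * T

    def negll(rho):
        B = np.eye(N) - rho * W
        sign, logdetB = np.linalg.slogdet(B)
        if sign <= 0:
            return np.inf
        ys = (Yd @ B.T).reshape(-1)
        Xs = np.einsum("ij,tjk->tik", B, Zd).reshape(NT, K)
        coef, _, _, _ = np.linalg.lstsq(Xs, ys, rcond=None)
        rss = float(((ys - Xs @ coef) ** 2).sum())
        if rss <= 0:
            return np.inf
        return 0.5 * NT * math.log(rss / NT) - T * logdetB

    best = None
    for r0 in rho_starts:
        res = optimize.minimize(
            negll,
            np.asarray([r0]),
            method="L-BFGS-B",
            bounds=[(-rho_bound, rho_bound)],
            options={"ftol": OPT_TOL, "gtol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    rho_hat = float(best.x[0])
    B = np.eye(N) - rho_hat * W
    _, logdetB = np.linalg.slogdet(B)
    ys = (Yd @ B.T).reshape(-1)
    Xs = np.einsum("ij,tjk->tik", B, Zd).reshape(NT, K)
    coef, _, _, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    rss = float(((ys - Xs @ coef) ** 2).sum())
    # demeaning removes one df per landscape
    df = N * (T - 1) - K
    s2 = rss / df
    vcov = s2 * np.linalg.inv(Xs.T @ Xs)
    ll = -0.5 * NT * (math.log(2.0 * math.pi) + 1.0) - 0.5 * NT * math.log(rss / NT) + T * logdetB
    return SpatialFEFit(
        names=list(names) if names is not None else [f"x{i}" for i in range(K)],
        params=coef,
        rho=rho_hat,
        sigma2_nu=s2,
        loglik=float(ll),
        vcov=vcov,
        se=np.sqrt(np.diag(vcov)),
        converged=bool(best.success),
        n_obs=NT,
        diagnostics={"rss": rss},
    )


def hausman_test(
    fe: SpatialFEFit, re: SpatialREFit, alpha: float = 0.05
) -> HausmanResult:
    """Classic Hausman comparison of the shared time-variant coefficients.

    H = (b_FE - b_RE)' (V_FE - V_RE)^{-1} (b_FE - b_RE) ~ chi2(dof).  A
    symmetric pseudo-inverse is substituted (and flagged) when the variance
    difference is not positive definite.
    """
    shared = [n for n in fe.names if n in re.names]
    if not shared:
        raise ValueError("no shared coefficients between FE and RE fits")
    i_fe = [fe.names.index(n) for n in shared]
    i_re = [re.names.index(n) for n in shared]
    d = fe.params[i_fe] - re.params[i_re]
    V = fe.vcov[np.ix_(i_fe, i_fe)] - re.vcov[np.ix_(i_re, i_re)]
    V = 0.5 * (V + V.T)
    used_pinv = False
    try:
        L = np.linalg.cholesky(V)
        sol = np.linalg.solve(V, d)
    except np.linalg.LinAlgError:
        used_pinv = True
        sol = pinvh(V) @ d
    stat = float(max(0.0, d @ sol))
    dof = len(shared)
    p = float(stats.chi2.sf(stat, dof))
    return HausmanResult(
        statistic=stat,
        dof=dof,
        p=p,
        decision="fixed" if p < alpha else "random",
        used_pseudo_inverse=used_pinv,
        shared=shared,
    )


def coef_table(fit) -> "pd.DataFrame":
    """Labelled inference table: coefficient, SE, z, two-sided p per row."""
    import pandas as pd

    if isinstance(fit, SpatialREFit):
        z = fit.z
        p = fit.p
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = fit.params / fit.se
        p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "coefficient": fit.params,
            "std_error": fit.se,
            "z": z,
            "p": p,
        },
        index=pd.Index(fit.names, name="covariate"),
    )
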