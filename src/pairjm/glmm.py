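"""Maximum-likelihood logistic random-intercept models by adaptive
Gauss-Hermite quadrature.

Fits univariate, bivariate, and (as a testing oracle) up-to-trivariate joint
models in which each outcome has its own fixed-effect vector and the
clinician-level random intercepts are jointly multivariate normal with
unstructured covariance D. Conditional on the intercepts the outcomes are
independent Bernoulli variables on the logit scale, so the cluster likelihood
is a p-dimensional integral; it is evaluated by Gauss-Hermite quadrature
adapted to each cluster's conditional mode and curvature.

The marginal score is computed by Fisher's identity (the posterior
expectation of the complete-data score over the same quadrature nodes),
which also yields the per-cluster score vectors needed by the pairwise
pseudo-likelihood sandwich estimator. Per-cluster Hessian blocks are
obtained by central finite differences of the per-cluster scores.

The random-intercept covariance is parameterized by its log-Cholesky factor
(log of the diagonal), so D is positive definite throughout optimization;
boundary fits (variance near zero, correlation near one) are flagged,
never errored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .design import COEF_LABELS, build_design

_LOG2PI = np.log(2.0 * np.pi)
_CHUNK_BUDGET = 4.0e7  # floats per (rows x nodes x dim) block


@dataclass
class ModelSpec:
    """Which outcomes to model jointly, with which fixed-effect terms.

    outcomes: 1-based outcome indices (length 1, 2, or 3)
    terms: design term labels (default: all 13)
    n_quad: quadrature nodes per random-effect dimension
    """

    outcomes: tuple[int, ...]
    terms: list[str] | None = None
    n_quad: int = 15
    cluster: str = "clinician_id"

    @property
    def labels(self) -> list[str]:
        return list(self.terms) if self.terms is not None else list(COEF_LABELS)


@dataclass
class FitResult:
    outcomes: tuple[int, ...]
    labels: list[str]
    beta: np.ndarray            # (p_dim, k)
    D: np.ndarray               # (p_dim, p_dim)
    theta: np.ndarray           # full parameter vector (betas then log-chol)
    loglik: float
    converged: bool
    grad_norm: float
    n_iter: int
    flags: list[str]
    cluster_ids: np.ndarray
    per_cluster_loglik: np.ndarray          # (J,)
    per_cluster_scores: np.ndarray          # (J, P)
    per_cluster_hessians: np.ndarray | None  # (J, P, P), loglik Hessians
    info: np.ndarray | None     # total observed information (P, P)
    X: np.ndarray = field(repr=False, default=None)
    Y: np.ndarray = field(repr=False, default=None)
    cluster_index: np.ndarray = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return self.beta.shape[1]

    @property
    def p_dim(self) -> int:
        return self.beta.shape[0]

    @property
    def n_params(self) -> int:
        return self.theta.size

    @property
    def beta_indices(self) -> np.ndarray:
        return np.arange(self.p_dim * self.k)

    @property
    def pair(self) -> tuple[int, ...]:
        return tuple(self.outcomes)

    @property
    def vcov(self) -> np.ndarray:
        """Model-based covariance (inverse observed information)."""
        if self.info is None:
            raise ValueError("information matrix not computed")
        return np.linalg.inv(self.info)

    @property
    def corr(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.D))
        return self.D / np.outer(sd, sd)


# ---------------------------------------------------------------------------
# parameterization helpers

def n_lam(p: int) -> int:
    return p * (p + 1) // 2


def lam_diag_mask(p: int) -> np.ndarray:
    mask = np.zeros(n_lam(p), dtype=bool)
    m = 0
    for i in range(p):
        for j in range(i + 1):
            if i == j:
                mask[m] = True
            m += 1
    return mask


def lam_to_chol(lam: np.ndarray, p: int) -> np.ndarray:
    """Lower-triangular Cholesky factor; diagonal entries are exp(lam)."""
    L = np.zeros((p, p))
    m = 0
    for i in range(p):
        for j in range(i + 1):
            L[i, j] = np.exp(lam[m]) if i == j else lam[m]
            m += 1
    return L


def chol_to_lam(L: np.ndarray) -> np.ndarray:
    p = L.shape[0]
    lam = []
    for i in range(p):
        for j in range(i + 1):
            lam.append(np.log(L[i, i]) if i == j else L[i, j])
    return np.array(lam)


def d_D_d_lam(L: np.ndarray) -> np.ndarray:
    """Stack of dD/dlam_m matrices for D = L L'."""
    p = L.shape[0]
    out = np.zeros((n_lam(p), p, p))
    m = 0
    for i in range(p):
        for j in range(i + 1):
            E = np.zeros((p, p))
            E[i, j] = L[i, i] if i == j else 1.0  # chain rule for log-diag
            dD = E @ L.T
            out[m] = dD + dD.T
            m += 1
    return out


def _gh_grid(n: int, p: int):
    z1, w1 = np.polynomial.hermite.hermgauss(n)
    grids = np.meshgrid(*([z1] * p), indexing="ij")
    Z = np.column_stack([g.ravel() for g in grids])          # (K, p)
    logw = np.log(w1)
    logwt = sum(np.meshgrid(*([logw] * p), indexing="ij")[d].ravel()
                for d in range(p))
    logwt = logwt + (Z ** 2).sum(axis=1)                     # w * exp(|z|^2)
    return Z, logwt


# ---------------------------------------------------------------------------
# data preparation

@dataclass
class _Prep:
    X: np.ndarray               # (N, k), rows sorted by cluster
    Y: np.ndarray               # (N, p_dim)
    cl_idx: np.ndarray          # (N,) 0-based cluster index
    starts: np.ndarray          # (J,) reduceat boundaries
    cluster_ids: np.ndarray     # (J,)
    k: int
    p_dim: int


def _prepare(data, spec: ModelSpec) -> _Prep:
    df = data.df
    if df[spec.cluster].isna().any():
        raise ValueError("cluster identifier contains missing values")
    order = np.argsort(df[spec.cluster].to_numpy(float), kind="stable")
    df2 = df.iloc[order].reset_index(drop=True)
    cl = df2[spec.cluster].to_numpy(float)
    cluster_ids, starts = np.unique(cl, return_index=True)
    cl_idx = np.searchsorted(cluster_ids, cl)
    X = build_design(df2, spec.terms)
    ycols = [f"y{r}" for r in spec.outcomes]
    Y = df2[ycols].to_numpy(float)
    return _Prep(X, Y, cl_idx, starts, cluster_ids, X.shape[1], len(ycols))


def _grpsum(arr: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(arr, starts, axis=0)


# ---------------------------------------------------------------------------
# conditional modes

def _find_modes(eta0, Y, Dinv, prep: _Prep, b0=None, max_iter=60, tol=1e-9):
    J, pd_ = len(prep.starts), prep.p_dim
    b = np.zeros((J, pd_)) if b0 is None else b0.copy()
    eye = np.eye(pd_)
    for _ in range(max_iter):
        eta = eta0 + b[prep.cl_idx]
        mu = expit(eta)
        g = _grpsum(Y - mu, prep.starts) - b @ Dinv
        if np.max(np.abs(g)) < tol:
            break
        w = _grpsum(mu * (1.0 - mu), prep.starts)
        H = Dinv[None, :, :] + eye[None, :, :] * w[:, None, :]
        step = np.linalg.solve(H, g[..., None])[..., 0]
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        scale = np.where(norm > 5.0, 5.0 / np.maximum(norm, 1e-12), 1.0)
        step = step * scale
        b = b + step
    return b


# ---------------------------------------------------------------------------
# adaptive quadrature evaluation

def _eval(theta, prep: _Prep, n_quad: int, mode_cache: dict,
          want_percluster: bool = False):
    """Negative log-likelihood, its gradient, and optionally per-cluster
    log-likelihoods and score vectors, all by adaptive Gauss-Hermite."""
    k, pd_ = prep.k, prep.p_dim
    J = len(prep.starts)
    nb = pd_ * k
    beta = theta[:nb].reshape(pd_, k)
    lam = theta[nb:]
    L = lam_to_chol(lam, pd_)
    D = L @ L.T
    Dinv = np.linalg.inv(D)
    _, logdetD = np.linalg.slogdet(D)

    eta0 = prep.X @ beta.T                                   # (N, pd)
    modes = _find_modes(eta0, prep.Y, Dinv, prep, b0=mode_cache.get("b"))
    mode_cache["b"] = modes

    mu_m = expit(eta0 + modes[prep.cl_idx])
    w_m = _grpsum(mu_m * (1.0 - mu_m), prep.starts)
    Hm = Dinv[None, :, :] + np.eye(pd_)[None, :, :] * w_m[:, None, :]
    Am = np.linalg.inv(Hm)
    Cm = np.linalg.cholesky(Am)                              # (J, pd, pd)
    logdetC = np.sum(np.log(np.diagonal(Cm, axis1=1, axis2=2)), axis=1)

    Z, logwt = _gh_grid(n_quad, pd_)
    K = Z.shape[0]
    # node locations per cluster: (J, K, pd)
    B = modes[:, None, :] + np.sqrt(2.0) * np.einsum("jab,kb->jka", Cm, Z)

    N = prep.X.shape[0]
    quad = np.einsum("jka,ab,jkb->jk", B, Dinv, B)
    logphi = -0.5 * (pd_ * _LOG2PI + logdetD + quad)
    single_pass = N * K * pd_ <= _CHUNK_BUDGET

    h = np.empty((J, K))
    mu_nodes = None
    if single_pass:
        eta = eta0[:, None, :] + B[prep.cl_idx]
        mu_nodes = expit(eta)
        ll_rows = (prep.Y[:, None, :] * eta - np.logaddexp(0.0, eta)).sum(-1)
        h[:] = _grpsum(ll_rows, prep.starts)
        del eta, ll_rows
    else:
        chunk = max(1, int(_CHUNK_BUDGET / max(N * pd_, 1)))
        for s in range(0, K, chunk):
            e = min(s + chunk, K)
            eta = eta0[:, None, :] + B[prep.cl_idx, s:e, :]
            ll_rows = (prep.Y[:, None, :] * eta
                       - np.logaddexp(0.0, eta)).sum(-1)
            h[:, s:e] = _grpsum(ll_rows, prep.starts)
    h = h + logphi

    ll_j = (0.5 * pd_ * np.log(2.0) + logdetC
            + logsumexp(h + logwt[None, :], axis=1))
    nll = -float(ll_j.sum())

    # posterior node weights
    omega = np.exp(h + logwt[None, :] - (ll_j - 0.5 * pd_ * np.log(2.0)
                                         - logdetC)[:, None])
    omega = omega / omega.sum(axis=1, keepdims=True)

    # Fisher-identity scores
    m_rows = np.zeros((N, pd_))          # posterior-weighted residual per row
    if single_pass:
        m_rows = np.einsum("nkp,nk->np", prep.Y[:, None, :] - mu_nodes,
                           omega[prep.cl_idx])
    else:
        for s in range(0, K, chunk):
            e = min(s + chunk, K)
            eta = eta0[:, None, :] + B[prep.cl_idx, s:e, :]
            resid = prep.Y[:, None, :] - expit(eta)
            m_rows += np.einsum("nkp,nk->np", resid, omega[prep.cl_idx, s:e])

    S2 = np.einsum("jk,jka,jkb->jab", omega, B, B)           # E[b b' | y]
    scoreD = 0.5 * (Dinv @ S2 @ Dinv - Dinv[None, :, :])     # (J, pd, pd)
    dD = d_D_d_lam(L)                                        # (nlam, pd, pd)
    s_lam = np.einsum("jab,mab->jm", scoreD, dD)             # (J, nlam)

    grad_beta = np.einsum("nk,np->pk", prep.X, m_rows)       # (pd, k)
    grad = -np.concatenate([grad_beta.ravel(), s_lam.sum(axis=0)])

    if not want_percluster:
        return nll, grad
    # per-cluster score vectors, columns [beta_1, ..., beta_pd, lam]
    s_beta = np.empty((J, pd_ * k))
    for r in range(pd_):
        s_beta[:, r * k:(r + 1) * k] = _grpsum(
            m_rows[:, r:r + 1] * prep.X, prep.starts)
    scores = np.concatenate([s_beta, s_lam], axis=1)
    return nll, grad, ll_j, scores


def per_cluster_scores(theta, prep: _Prep, n_quad: int,
                       mode_cache: dict | None = None) -> np.ndarray:
    cache = {} if mode_cache is None else mode_cache
    _, _, _, scores = _eval(theta, prep, n_quad, cache, want_percluster=True)
    return scores


def per_cluster_hessians(theta, prep: _Prep, n_quad: int,
                         mode_cache: dict | None = None) -> np.ndarray:
    """Per-cluster Hessians of the log-likelihood by central finite
    differences of the per-cluster scores, step 1e-5 * (1 + |theta|)."""
    P = theta.size
    J = len(prep.starts)
    cache = {} if mode_cache is None else mode_cache
    H = np.zeros((J, P, P))
    for m in range(P):
        hstep = 1e-5 * (1.0 + abs(theta[m]))
        tp = theta.copy(); tp[m] += hstep
        tm = theta.copy(); tm[m] -= hstep
        sp = per_cluster_scores(tp, prep, n_quad, cache)
        smn = per_cluster_scores(tm, prep, n_quad, cache)
        H[:, m, :] = (sp - smn) / (2.0 * hstep)
    return (H + H.transpose(0, 2, 1)) / 2.0


# ---------------------------------------------------------------------------
# public likelihood evaluation

def loglik_joint(beta, D, data, spec: ModelSpec) -> float:
    """Marginal log-likelihood at the given fixed effects and random-intercept
    covariance. A (numerically) zero D degenerates to independent ordinary
    logistic regressions evaluated at b = 0."""
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    prep = _prepare(data, spec)
    eta0 = prep.X @ beta.T
    if not np.all(np.isfinite(eta0)):
        bad = np.unique(prep.cluster_ids[prep.cl_idx[
            ~np.isfinite(eta0).all(axis=1)]])
        raise ValueError(f"non-finite linear predictor in clusters {bad}")
    if np.abs(D).max() < 1e-12:
        return float((prep.Y * eta0 - np.logaddexp(0.0, eta0)).sum())
    w = np.linalg.eigvalsh(D)
    if w.min() <= 0:
        raise ValueError(f"D must be positive definite (eigenvalue {w.min():.3g})")
    theta = np.concatenate([beta.ravel(), chol_to_lam(np.linalg.cholesky(D))])
    nll, _ = _eval(theta, prep, spec.n_quad, {})
    return -nll


def loglik_bivariate(beta, D, data, spec: ModelSpec) -> float:
    if len(spec.outcomes) != 2:
        raise ValueError("spec must name exactly two outcomes")
    return loglik_joint(beta, D, data, spec)


# ---------------------------------------------------------------------------
# fitting

def _start_values(prep: _Prep) -> np.ndarray:
    betas = []
    for r in range(prep.p_dim):
        try:
            res = sm.GLM(prep.Y[:, r], prep.X,
                         family=sm.families.Binomial()).fit(maxiter=100)
            b = np.asarray(res.params)
            if not np.all(np.isfinite(b)):
                raise ValueError
        except Exception:
            b = np.zeros(prep.k)
        betas.append(np.clip(b, -10, 10))
    L0 = np.linalg.cholesky(0.5 * np.eye(prep.p_dim))
    return np.concatenate([np.concatenate(betas), chol_to_lam(L0)])


def fit_joint(data, spec: ModelSpec, compute_hessians: bool = True,
              theta0: np.ndarray | None = None) -> FitResult:
    """Quasi-Newton ML fit. Starting values are outcome-wise ordinary
    logistic regressions with random-intercept variances 0.5, covariances 0
    (or an explicit `theta0`, e.g. a previous replicate's solution).
    Non-convergence is flagged on the result, never silently dropped."""
    pd_ = len(spec.outcomes)
    if pd_ > 3:
        raise ValueError(
            "direct joint fits are limited to 3 outcomes; use the pairwise "
            "pseudo-likelihood path for higher dimensions"
        )
    prep = _prepare(data, spec)
    if theta0 is None:
        theta0 = _start_values(prep)
    # box constraints keep D invertible: log-sd floored so a collapsing
    # variance stops at ~1e-3 (the boundary-flag threshold) instead of
    # underflowing to a singular covariance
    nb = pd_ * prep.k
    bounds = [(-50.0, 50.0)] * nb
    for is_diag in lam_diag_mask(pd_):
        bounds.append((np.log(0.03), 4.0) if is_diag else (-25.0, 25.0))
    theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
    cache: dict = {}
    res = minimize(_eval, theta0, args=(prep, spec.n_quad, cache),
                   jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-6})
    theta = res.x
    nll, grad, ll_j, scores = _eval(theta, prep, spec.n_quad, cache,
                                    want_percluster=True)
    grad_norm = float(np.max(np.abs(grad)))
    converged = bool(res.success) or grad_norm < 1e-4

    nb = pd_ * prep.k
    beta = theta[:nb].reshape(pd_, prep.k)
    L = lam_to_chol(theta[nb:], pd_)
    D = L @ L.T

    flags = []
    if not converged:
        flags.append("non_convergence")
    var = np.diag(D)
    for r, o in enumerate(spec.outcomes):
        if var[r] < 1e-3:
            flags.append(f"boundary_variance_y{o}")
    if pd_ > 1:
        sd = np.sqrt(var)
        corr = D / np.outer(sd, sd)
        off = corr[np.triu_indices(pd_, 1)]
        if np.any(np.abs(off) > 0.99):
            flags.append("boundary_correlation")

    hess = info = None
    if compute_hessians:
        hess = per_cluster_hessians(theta, prep, spec.n_quad, cache)
        info = -hess.sum(axis=0)

    return FitResult(
        outcomes=tuple(spec.outcomes), labels=spec.labels,
        beta=beta, D=D, theta=theta, loglik=-nll,
        converged=converged, grad_norm=grad_norm,
        n_iter=int(res.nit), flags=flags,
        cluster_ids=prep.cluster_ids, per_cluster_loglik=ll_j,
        per_cluster_scores=scores, per_cluster_hessians=hess, info=info,
        X=prep.X, Y=prep.Y, cluster_index=prep.cl_idx,
    )


def fit_univariate(data, spec: ModelSpec, **kw) -> FitResult:
    if len(spec.outcomes) != 1:
        raise ValueError("univariate spec must name exactly one outcome")
    return fit_joint(data, spec, **kw)


def fit_bivariate(data, spec: ModelSpec, **kw) -> FitResult:
    if len(spec.outcomes) != 2:
        raise ValueError("bivariate spec must name exactly two outcomes")
    return fit_joint(data, spec, **kw)


def full_joint_fit(data, outcomes, terms=None, n_quad: int = 7, **kw) -> FitResult:
    """Small-p direct joint ML fit (testing oracle; refuses p > 3)."""
    return fit_joint(data, ModelSpec(tuple(outcomes), terms=terms,
                                     n_quad=n_quad), **kw)
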