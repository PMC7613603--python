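"""Pairwise pseudo-likelihood inference for the joint multivariate model.

With p outcomes, all Q = p(p-1)/2 bivariate random-intercept models are
fitted separately; the stacked estimate maximizes the pseudo-log-likelihood
(the sum of the pairwise log-likelihoods), is asymptotically normal with
sandwich covariance H^{-1} G H^{-1}, and each outcome's p-1 duplicate
coefficient vectors are averaged into the joint-model estimate by the 0 /
1/(p-1) weight matrix A:

    beta* = A beta_stacked,      Sigma* = A Omega A'

where Omega is the sandwich covariance of the stacked coefficients. Across
multiply imputed datasets the per-imputation (beta*, Sigma*) are pooled by
Rubin's rules, and joint covariate effects are tested with Wald statistics
(L beta)' (L V L')^{-1} (L beta) against chi-squared with rows(L) degrees
of freedom.

Two sandwich constructions are provided. `sandwich_empirical` (the default)
builds H from the per-cluster Hessians and G from the per-cluster scores of
each pairwise fit, aligning clusters across pairs so that the cross-pair
blocks of G carry the dependence between pairs sharing an outcome.
`sandwich_literal_recipe` follows the originally described step-by-step recipe literally,
in which the middle matrix is T = Z D Z' with no inverse or Bernoulli
residual-variance term; as printed, its "J" blocks are not Hessian
analogues, so the routine emits a warning and is intended for side-by-side
comparison only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import COEF_LABELS
from .glmm import FitResult


@dataclass(frozen=True)
class PairIndex:
    """Lexicographic enumeration of outcome pairs (r, s), r < s, 1-based."""

    p: int
    pairs: tuple[tuple[int, int], ...]

    @property
    def Q(self) -> int:
        return len(self.pairs)

    def position(self, pair: tuple[int, int]) -> int:
        return self.pairs.index(tuple(pair))


def enumerate_pairs(p: int) -> PairIndex:
    if p < 2:
        raise ValueError("pairwise modeling requires at least 2 outcomes")
    pairs = tuple((r, s) for r in range(1, p) for s in range(r + 1, p + 1))
    return PairIndex(p=p, pairs=pairs)


@dataclass
class StackedEstimates:
    """The 2kQ stacked coefficient vector with its variance machinery.

    Block order: pairs in PairIndex order; within a pair, outcome r's k
    coefficients then outcome s's. `omega` is the finite-sample sandwich
    covariance of the stacked coefficients; `H`, `G` are the per-cluster
    normalized bread and meat over the full per-pair parameter vectors
    (coefficients plus covariance parameters).
    """

    index: PairIndex
    k: int
    fits: list[FitResult]
    beta_stacked: np.ndarray
    omega: np.ndarray | None = None
    H: np.ndarray | None = field(default=None, repr=False)
    G: np.ndarray | None = field(default=None, repr=False)
    engine: str | None = None

    @property
    def n_stacked(self) -> int:
        return 2 * self.k * self.index.Q


def stack(fits: list[FitResult], index: PairIndex, k: int | None = None
          ) -> StackedEstimates:
    """Order the pairwise fits lexicographically and stack their coefficient
    vectors. Raises if any pair is missing or duplicated."""
    by_pair = {}
    for f in fits:
        if f.pair in by_pair:
            raise ValueError(f"duplicate fit for pair {f.pair}")
        by_pair[f.pair] = f
    missing = [pr for pr in index.pairs if pr not in by_pair]
    extra = [pr for pr in by_pair if pr not in index.pairs]
    if missing or extra:
        raise ValueError(f"missing pairs {missing}, unexpected pairs {extra}")
    ordered = [by_pair[pr] for pr in index.pairs]
    ks = {f.k for f in ordered}
    if k is None:
        (k,) = ks
    elif ks != {k}:
        raise ValueError(f"fits have {ks} coefficients per outcome, expected {k}")
    beta = np.concatenate([f.beta.ravel() for f in ordered])
    return StackedEstimates(index=index, k=k, fits=ordered, beta_stacked=beta)


def build_weight_matrix(p: int, k: int) -> np.ndarray:
    """The pk x 2kQ averaging matrix A: the row for coefficient c of outcome
    r has 1/(p-1) at the p-1 stacked positions where (r, c) occurs."""
    if p < 2 or k < 1:
        raise ValueError("need p >= 2 outcomes and k >= 1 coefficients")
    index = enumerate_pairs(p)
    A = np.zeros((p * k, 2 * k * index.Q))
    w = 1.0 / (p - 1)
    for qi, (r, s) in enumerate(index.pairs):
        off = qi * 2 * k
        for c in range(k):
            A[(r - 1) * k + c, off + c] = w
            A[(s - 1) * k + c, off + k + c] = w
    return A


# ---------------------------------------------------------------------------
# sandwich covariance of the stacked estimate

def _param_layout(stacked: StackedEstimates):
    """Offsets of each pair's full parameter block and of the coefficient
    entries inside the concatenated parameter vector."""
    offsets, beta_cols = [], []
    pos = 0
    for f in stacked.fits:
        offsets.append(pos)
        beta_cols.append(pos + f.beta_indices)
        pos += f.n_params
    return offsets, np.concatenate(beta_cols), pos


def sandwich_empirical(stacked: StackedEstimates) -> StackedEstimates:
    """Cluster-robust sandwich from per-cluster scores and Hessians.

    The bread is block-diagonal in the pairwise observed informations; the
    meat sums g_i g_i' over clusters, where g_i concatenates cluster i's
    score across all pairs (zero blocks where a cluster contributes no data
    to a pair). Returns the same object with omega/H/G attached; omega is
    restricted to the stacked coefficients.
    """
    fits = stacked.fits
    for f in fits:
        if f.per_cluster_hessians is None:
            raise ValueError(
                f"fit for pair {f.pair} lacks per-cluster Hessians"
            )
    all_ids = np.unique(np.concatenate([f.cluster_ids for f in fits]))
    n_cl = len(all_ids)
    offsets, beta_cols, total = _param_layout(stacked)

    info = np.zeros((total, total))
    g = np.zeros((n_cl, total))
    for f, off in zip(fits, offsets):
        sl = slice(off, off + f.n_params)
        info[sl, sl] = -f.per_cluster_hessians.sum(axis=0)
        rows = np.searchsorted(all_ids, f.cluster_ids)
        g[rows, sl] = f.per_cluster_scores
    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"singular bread matrix H (condition number {cond:.3g})"
        )
    binv = np.linalg.inv(info)
    gsum = g.T @ g
    omega_full = binv @ gsum @ binv           # finite-sample Var(theta_hat)
    omega_full = (omega_full + omega_full.T) / 2.0

    stacked.omega = omega_full[np.ix_(beta_cols, beta_cols)]
    stacked.H = info / n_cl
    stacked.G = gsum / n_cl
    stacked.engine = "empirical"
    return stacked


def sandwich_literal_recipe(stacked: StackedEstimates) -> StackedEstimates:
    """The literal published recipe: per pair, J_q = sum_i X_i' T_i X_i and
    K_q = [X_1'T_1, ..., X_N'T_N] with T_i = Z_i D Z_i' (here Z_i = I, so
    T_i = D); J block-diagonal, K row-stacked with columns aligned on
    subjects; H = J/N, G = K K'/N; Omega = H^{-1} G H^{-1}.

    As printed the middle matrix omits any inverse or Bernoulli-variance
    term, so J is not a Hessian analogue; a warning is emitted and the
    result should be compared against `sandwich_empirical`.
    """
    warnings.warn(
        "the verbatim recipe uses T = Z D Z' with no inverse or residual "
        "variance term; use sandwich_empirical for standard cluster-robust "
        "inference",
        UserWarning, stacklevel=2,
    )
    fits = stacked.fits
    k = stacked.k
    n_subjects = {f.X.shape[0] for f in fits}
    if len(n_subjects) != 1:
        raise ValueError("pairs were fitted on differing subject sets")
    (N,) = n_subjects
    nb = 2 * k
    Q = stacked.index.Q
    J = np.zeros((nb * Q, nb * Q))
    K = np.zeros((nb * Q, 2 * N))
    for qi, f in enumerate(fits):
        D = f.D
        xxt = f.X.T @ f.X                     # sum_i x_i x_i'
        Jq = np.kron(D, xxt)                  # sum_i kron(T_i, x_i x_i')
        sl = slice(qi * nb, (qi + 1) * nb)
        J[sl, sl] = Jq
        # K_q block for subject i is X_i' T_i = kron(T_i, x_i), shape 2k x 2;
        # columns are subject-major: [i=1 cols(2), i=2 cols(2), ...]
        Kq = np.empty((nb, 2 * N))
        for c in range(2):
            Kq[:, c::2] = np.kron(D[:, [c]], f.X.T)
        K[sl, :] = Kq
    cond = np.linalg.cond(J)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"singular J in the verbatim recipe (condition number {cond:.3g})"
        )
    H = J / N
    G = (K @ K.T) / N
    Hinv = np.linalg.inv(H)
    omega = Hinv @ G @ Hinv
    stacked.omega = (omega + omega.T) / 2.0
    stacked.H = H
    stacked.G = G
    stacked.engine = "literal"
    return stacked


# ---------------------------------------------------------------------------
# combining, pooling, testing

@dataclass
class CombinedEstimates:
    """Averaged joint-model coefficients beta* (pk) with covariance Sigma*."""

    beta_star: np.ndarray
    sigma_star: np.ndarray
    p: int
    k: int
    m: int | str = "CC"

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.sigma_star))


def combine(A: np.ndarray, stacked: StackedEstimates) -> CombinedEstimates:
    """beta* = A beta_stacked, Sigma* = A Omega A'."""
    if A.shape[1] != stacked.beta_stacked.size:
        raise ValueError(
            f"weight matrix has {A.shape[1]} columns but the stacked vector "
            f"has {stacked.beta_stacked.size} entries"
        )
    if stacked.omega is None:
        raise ValueError("run a sandwich engine before combining")
    beta_star = A @ stacked.beta_stacked
    sigma_star = A @ stacked.omega @ A.T
    return CombinedEstimates(beta_star=beta_star,
                             sigma_star=(sigma_star + sigma_star.T) / 2.0,
                             p=stacked.index.p, k=stacked.k)


@dataclass
class PooledEstimates:
    """Rubin's-rules pooled estimates over M imputations.

    V = W + (1 + 1/M) B, with the full between-imputation covariance B
    retained so joint Wald tests can be formed from V.
    """

    beta_bar: np.ndarray
    W: np.ndarray
    B: np.ndarray
    M: int
    p: int
    k: int

    @property
    def V(self) -> np.ndarray:
        return self.W + (1.0 + 1.0 / self.M) * self.B

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.V))


def rubin_pool(per_imputation: list[CombinedEstimates]) -> PooledEstimates:
    M = len(per_imputation)
    if M < 2:
        raise ValueError("Rubin pooling needs M >= 2 imputations "
                         "(between-imputation variance is undefined)")
    shapes = {e.beta_star.shape for e in per_imputation}
    if len(shapes) != 1:
        raise ValueError("per-imputation estimates have differing shapes")
    betas = np.stack([e.beta_star for e in per_imputation])
    beta_bar = betas.mean(axis=0)
    W = np.mean([e.sigma_star for e in per_imputation], axis=0)
    dev = betas - beta_bar
    B = dev.T @ dev / (M - 1)
    return PooledEstimates(beta_bar=beta_bar, W=W, B=B, M=M,
                           p=per_imputation[0].p, k=per_imputation[0].k)


@dataclass(frozen=True)
class WaldSpec:
    L: np.ndarray
    label: str

    @property
    def df(self) -> int:
        return self.L.shape[0]


@dataclass(frozen=True)
class WaldResult:
    statistic: float
    df: int
    p_value: float
    label: str


def build_L(label: str, p: int, k: int,
            labels: list[str] | None = None) -> WaldSpec:
    """Selector matrix with one row per outcome picking that outcome's
    coefficient for `label` out of the pk combined vector."""
    labels = list(labels) if labels is not None else list(COEF_LABELS[:k])
    if label not in labels:
        raise ValueError(f"unknown coefficient label {label!r}; "
                         f"choose from {labels}")
    c = labels.index(label)
    L = np.zeros((p, p * k))
    for r in range(p):
        L[r, r * k + c] = 1.0
    return WaldSpec(L=L, label=label)


def wald_joint_test(spec: WaldSpec, beta: np.ndarray,
                    V: np.ndarray) -> WaldResult:
    """(L beta)'(L V L')^{-1}(L beta) against chi-squared with rows(L) df."""
    L = spec.L
    lb = L @ beta
    lvl = L @ V @ L.T
    cond = np.linalg.cond(lvl)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"L V L' is singular (condition number {cond:.3g})")
    stat = float(lb @ np.linalg.solve(lvl, lb))
    df = spec.df
    return WaldResult(statistic=stat, df=df,
                      p_value=float(stats.chi2.sf(stat, df)),
                      label=spec.label)


def concat_wald(specs: list[WaldSpec], label: str) -> WaldSpec:
    """Joint contrast over several coefficient labels (e.g. the three
    comorbidity-count contrasts tested simultaneously)."""
    return WaldSpec(L=np.vstack([s.L for s in specs]), label=label)


def fit_all_pairs(data, p: int, terms=None, n_quad: int = 15,
                  compute_hessians: bool = True,
                  theta0s: dict | None = None):
    """Fit every bivariate model for outcomes 1..p; returns {pair: fit}."""
    from .glmm import ModelSpec, fit_bivariate

    index = enumerate_pairs(p)
    fits = {}
    for pr in index.pairs:
        t0 = theta0s.get(pr) if theta0s else None
        fits[pr] = fit_bivariate(
            data, ModelSpec(pr, terms=terms, n_quad=n_quad),
            compute_hessians=compute_hessians, theta0=t0)
    return fits
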