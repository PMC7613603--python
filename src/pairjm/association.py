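"""Random-intercept covariance assembly, correlations, and PCA.

The full p x p random-intercept covariance D is never estimated directly:
each bivariate fit contributes a 2 x 2 block, so every outcome's variance is
estimated p-1 times (once per pair containing it) and every covariance
exactly once. Assembly averages the duplicate variances onto the diagonal
and maps each unique covariance to its off-diagonal cell. The assembled
matrix is symmetric by construction but not guaranteed positive
semidefinite; implied correlations outside [-1, 1] and negative eigenvalues
are flagged rather than silently repaired (a nearest-PSD projection is
available as an option).

Correlations follow corr(b_r, b_s) = sigma_brs / sqrt(sigma_br^2 sigma_bs^2)
and are tabulated with variances on the diagonal and correlations below it.

`pca_correlation` supports two conventions. "eigen" is the direct
eigendecomposition of the correlation matrix with proportions lambda_i /
trace. "column_standardized" treats the correlation matrix as a data matrix
of p observations, centers and scales its columns, and eigendecomposes the
resulting covariance (the convention of R's `prcomp(C, scale.=TRUE)`); this
is the construction that reproduces the reported first/second-component
percentages for the trial's published matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glmm import FitResult
from .pseudolik import PairIndex


@dataclass
class DMatrix:
    D: np.ndarray
    provenance: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.D.shape[0]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray         # descending
    loadings: np.ndarray            # eigenvectors scaled by sqrt(lambda)
    proportions: np.ndarray         # fraction of variation per component
    convention: str
    flags: list[str] = field(default_factory=list)

    @property
    def pct(self) -> np.ndarray:
        return 100.0 * self.proportions


def assemble_D(fits: list[FitResult], index: PairIndex) -> DMatrix:
    """Average each outcome's p-1 pairwise variances onto the diagonal and
    place each pair's covariance off-diagonal. Order of `fits` is
    irrelevant; a missing or duplicate pair raises."""
    by_pair = {}
    for f in fits:
        if f.pair in by_pair:
            raise ValueError(f"duplicate fit for pair {f.pair}")
        by_pair[f.pair] = f
    missing = [pr for pr in index.pairs if pr not in by_pair]
    if missing:
        raise ValueError(f"missing pairs {missing}")
    p = index.p
    D = np.zeros((p, p))
    contrib = {r: [] for r in range(1, p + 1)}
    provenance = {}
    for (r, s) in index.pairs:
        f = by_pair[(r, s)]
        D[r - 1, s - 1] = D[s - 1, r - 1] = f.D[0, 1]
        contrib[r].append((f.pair, f.D[0, 0]))
        contrib[s].append((f.pair, f.D[1, 1]))
        provenance[(r, s)] = [f.pair]
    for r in range(1, p + 1):
        D[r - 1, r - 1] = float(np.mean([v for _, v in contrib[r]]))
        provenance[(r, r)] = [pr for pr, _ in contrib[r]]
    flags = []
    v = np.diag(D)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = D / np.sqrt(np.outer(v, v))
    off = corr[~np.eye(p, dtype=bool)]
    if np.any(np.abs(off) > 1.0 + 1e-12):
        flags.append("implied_correlation_outside_unit_interval")
    if np.linalg.eigvalsh((D + D.T) / 2.0).min() < -1e-10:
        flags.append("not_positive_semidefinite")
    return DMatrix(D=D, provenance=provenance, flags=flags)


def average_over_imputations(d_list: list[DMatrix]) -> DMatrix:
    if not d_list:
        raise ValueError("no matrices to average")
    shapes = {d.D.shape for d in d_list}
    if len(shapes) != 1:
        raise ValueError("matrices have differing shapes")
    D = np.mean([d.D for d in d_list], axis=0)
    flags = []
    if np.linalg.eigvalsh((D + D.T) / 2.0).min() < -1e-10:
        flags.append("not_positive_semidefinite")
    return DMatrix(D=D, provenance={"averaged_over": len(d_list)}, flags=flags)


def corr_from_D(dm: DMatrix) -> pd.DataFrame:
    """Variance-correlation table: variances on the diagonal, correlations
    below, upper triangle blank. Zero-variance cells are reported as NaN
    and flagged on the input object."""
    D = dm.D
    p = D.shape[0]
    v = np.diag(D)
    out = np.full((p, p), np.nan)
    for r in range(p):
        out[r, r] = v[r]
        for s in range(r):
            if v[r] <= 0 or v[s] <= 0:
                if "zero_variance" not in dm.flags:
                    dm.flags.append("zero_variance")
                continue
            out[r, s] = D[r, s] / np.sqrt(v[r] * v[s])
    names = [f"y{r + 1}" for r in range(p)]
    return pd.DataFrame(out, index=names, columns=names)


def corr_matrix_from_D(dm: DMatrix) -> np.ndarray:
    """Full symmetric correlation matrix (unit diagonal)."""
    v = np.diag(dm.D)
    if np.any(v <= 0):
        raise ValueError("zero or negative variance on the diagonal")
    c = dm.D / np.sqrt(np.outer(v, v))
    np.fill_diagonal(c, 1.0)
    return (c + c.T) / 2.0


def nearest_psd_projection(dm: DMatrix, floor: float = 0.0) -> DMatrix:
    """Optional eigenvalue-clipped repair of a non-PSD assembly."""
    w, vec = np.linalg.eigh((dm.D + dm.D.T) / 2.0)
    D = (vec * np.maximum(w, floor)) @ vec.T
    return DMatrix(D=D, provenance=dict(dm.provenance, projected=True),
                   flags=[f for f in dm.flags if f != "not_positive_semidefinite"])


def _sign_fix(loadings: np.ndarray) -> np.ndarray:
    """Largest-magnitude loading of each component made positive."""
    out = loadings.copy()
    for c in range(out.shape[1]):
        col = out[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            out[:, c] = -col
    return out


def pca_correlation(corr: np.ndarray, convention: str = "eigen") -> PCAResult:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    p = corr.shape[0]
    flags = []
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        flags.append("non_unit_diagonal")

    if convention == "eigen":
        w, vec = np.linalg.eigh(corr)
        order = np.argsort(w)[::-1]
        w, vec = w[order], vec[:, order]
        proportions = w / np.trace(corr)
    elif convention == "column_standardized":
        x = corr - corr.mean(axis=0)
        sd = corr.std(axis=0, ddof=1)
        x = x / sd
        w, vec = np.linalg.eigh(x.T @ x / (p - 1))
        order = np.argsort(w)[::-1]
        w, vec = w[order], vec[:, order]
        proportions = w / w.sum()
    else:
        raise ValueError(f"unknown PCA convention {convention!r}")

    if w.min() < -1e-10:
        flags.append("negative_eigenvalues")
    loadings = _sign_fix(vec * np.sqrt(np.maximum(w, 0.0)))
    return PCAResult(eigenvalues=w, loadings=loadings,
                     proportions=proportions, convention=convention,
                     flags=flags)


def pca_table(res: PCAResult, names: list[str] | None = None) -> pd.DataFrame:
    p = len(res.eigenvalues)
    names = names or [f"y{r + 1}" for r in range(p)]
    head = pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(p)],
        "eigenvalue": res.eigenvalues,
        "proportion": res.proportions,
        "cumulative": np.cumsum(res.proportions),
    })
    load = pd.DataFrame(res.loadings, index=names,
                        columns=[f"PC{i + 1}" for i in range(p)])
    return head, load
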