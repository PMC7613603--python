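"""Two-level latent-normal multiple imputation by Gibbs sampling.

Binary covariates with missing values are represented by underlying
continuous normal variables thresholded at zero (probit-style, residual
variance fixed at 1 at the patient level for identifiability). Patient-level
latents get a clinician random intercept; clinician-level latents carry
their variability entirely through the clinician-level random effect (the
level-2 model has no separate residual term). The random effects of all
targets are jointly normal with unstructured covariance Sigma_b, which links
the two levels and the targets to one another:

    level 1 (patients):    Y*_ijl = x'_ijl beta1 + b^(1)_jl + e_ijl,
                           e ~ N(0, 1)
    level 2 (clinicians):  Y*_jl  = x'_jl  beta2 + b^(2)_jl
    (b^(1), b^(2))_jl ~ N(0, Sigma_b)

Fully observed covariates and all binary outcomes enter as predictors at
both levels (cluster means at level 2), making the imputation model
congenial with outcome analyses under missing-at-random missingness.
Observed cells constrain their latent to the half-line matching the
category; missing cells are free, and each saved imputation thresholds the
current latent at zero. Priors are flat for regression coefficients and
inverse-Wishart (identity scale, minimal degrees of freedom) for Sigma_b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart

from .datasets import TrialDataset, outcome_columns


@dataclass
class ImputationSpec:
    level1_targets: tuple[str, ...] = ("pat_sex",)
    level2_targets: tuple[str, ...] = ("clin_sex", "cadre")
    M: int = 20
    burn_in: int = 500
    between: int = 500
    seed: int = 0
    include_outcomes: bool = True

    def __post_init__(self):
        if self.M < 2:
            raise ValueError("M >= 2 imputations are required")
        if self.burn_in < 1 or self.between < 1:
            raise ValueError("burn_in and between must be >= 1")


@dataclass
class GibbsDesign:
    X1: np.ndarray          # (N, q1) patient-level predictors
    X2: np.ndarray          # (J, q2) clinician-level predictors
    cl_idx: np.ndarray      # (N,) 0-based clinician index (sorted rows)
    starts: np.ndarray
    n_j: np.ndarray         # (J,) cluster sizes
    y1: np.ndarray          # (N, r1) observed 0/1 or NaN
    y2: np.ndarray          # (J, r2) observed 0/1 or NaN
    order: np.ndarray       # row order applied to the input frame
    cluster_ids: np.ndarray
    names1: tuple[str, ...]
    names2: tuple[str, ...]

    @property
    def r1(self) -> int:
        return self.y1.shape[1]

    @property
    def r2(self) -> int:
        return self.y2.shape[1]


@dataclass
class GibbsState:
    lat1: np.ndarray        # (N, r1) latent values
    lat2: np.ndarray        # (J, r2)
    beta1: np.ndarray       # (q1, r1)
    beta2: np.ndarray       # (q2, r2)
    b1: np.ndarray          # (J, r1) clinician effects on level-1 latents
    Sigma_b: np.ndarray     # (r1+r2, r1+r2)

    def b2(self, design: GibbsDesign) -> np.ndarray:
        """Level-2 random effects are the level-2 latent residuals."""
        return self.lat2 - design.X2 @ self.beta2


@dataclass
class ImputedStack:
    datasets: list[TrialDataset]
    trace: pd.DataFrame

    @property
    def M(self) -> int:
        return len(self.datasets)


def _prune_collinear(X: np.ndarray) -> np.ndarray:
    """Drop predictor columns beyond the column rank (QR with pivoting),
    always keeping the leading intercept. Collinearity is common in small
    simulated datasets (e.g. hospital-level indicators coinciding)."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * 1e-6
    keep = sorted(piv[: int((diag > tol).sum())])
    if 0 not in keep:
        keep = [0] + keep[:-1]
    return X[:, keep]


def _psd_sqrt(m: np.ndarray) -> np.ndarray:
    """Symmetric square root with eigenvalues floored at zero; a robust
    stand-in for Cholesky on nearly singular posterior covariances."""
    m = (np.atleast_2d(m) + np.atleast_2d(m).T) / 2.0
    w, v = np.linalg.eigh(m)
    return v * np.sqrt(np.maximum(w, 0.0))


def _rtruncnorm(rng, mean, sd, side):
    """Truncated-normal draws: side +1 -> [0, inf), -1 -> (-inf, 0),
    0 -> unconstrained. Vectorized inverse-CDF sampling."""
    u = rng.random(np.shape(mean))
    z0 = ndtr(-np.asarray(mean) / sd)        # P(x < 0)
    lo = np.where(side > 0, z0, 0.0)
    hi = np.where(side < 0, z0, 1.0)
    uu = np.clip(lo + u * (hi - lo), 1e-15, 1.0 - 1e-15)
    return mean + sd * ndtri(uu)


def build_gibbs_design(data: TrialDataset, spec: ImputationSpec) -> GibbsDesign:
    df = data.df
    if df["clinician_id"].isna().any():
        raise ValueError("exclude rows without clinician id before imputing")
    order = np.argsort(df["clinician_id"].to_numpy(float), kind="stable")
    d = df.iloc[order].reset_index(drop=True)
    cl = d["clinician_id"].to_numpy(float)
    cluster_ids, starts = np.unique(cl, return_index=True)
    cl_idx = np.searchsorted(cluster_ids, cl)
    n_j = np.diff(np.r_[starts, len(d)])

    for t in spec.level1_targets + spec.level2_targets:
        col = d[t]
        obs = col.dropna()
        if len(obs) == 0:
            raise ValueError(f"target {t!r} has no observed values")
        if not np.isin(obs.to_numpy(float), (0.0, 1.0)).all():
            raise ValueError(f"target {t!r} is not binary 0/1")

    ycols = outcome_columns(data.p) if spec.include_outcomes else []
    pred1 = ["time_months", "arm", "workload", "malaria", "age_group"]
    x1_cols = [np.ones(len(d))]
    for c in pred1:
        x1_cols.append(d[c].to_numpy(float))
    x1_cols.append(d["time_months"].to_numpy(float) * d["arm"].to_numpy(float))
    for lvl in (0, 1, 2):
        x1_cols.append((d["comorbid"].to_numpy(float) == lvl).astype(float))
    for c in ycols:
        x1_cols.append(d[c].to_numpy(float))
    X1 = np.column_stack(x1_cols)
    if np.isnan(X1).any():
        raise ValueError("level-1 predictors contain missing values")
    X1 = _prune_collinear(X1)

    def cmean(col):
        return np.add.reduceat(col, starts) / n_j

    x2_cols = [np.ones(len(cluster_ids)),
               cmean(d["time_months"].to_numpy(float)),
               d["arm"].to_numpy(float)[starts],
               d["workload"].to_numpy(float)[starts],
               d["malaria"].to_numpy(float)[starts]]
    for c in ycols:
        x2_cols.append(cmean(d[c].to_numpy(float)))
    X2 = _prune_collinear(np.column_stack(x2_cols))

    y1 = d[list(spec.level1_targets)].to_numpy(float)
    y2 = np.column_stack([d[t].to_numpy(float)[starts]
                          for t in spec.level2_targets])
    return GibbsDesign(X1=X1, X2=X2, cl_idx=cl_idx, starts=starts, n_j=n_j,
                       y1=y1, y2=y2, order=order, cluster_ids=cluster_ids,
                       names1=tuple(spec.level1_targets),
                       names2=tuple(spec.level2_targets))


def init_state(design: GibbsDesign) -> GibbsState:
    J = len(design.cluster_ids)
    lat1 = np.where(np.isnan(design.y1), 0.0,
                    np.where(design.y1 > 0, 0.5, -0.5))
    lat2 = np.where(np.isnan(design.y2), 0.0,
                    np.where(design.y2 > 0, 0.5, -0.5))
    q1, q2 = design.X1.shape[1], design.X2.shape[1]
    beta1 = np.linalg.lstsq(design.X1, lat1, rcond=None)[0]
    beta2 = np.linalg.lstsq(design.X2, lat2, rcond=None)[0]
    d = design.r1 + design.r2
    return GibbsState(lat1=lat1, lat2=lat2, beta1=beta1, beta2=beta2,
                      b1=np.zeros((J, design.r1)), Sigma_b=np.eye(d))


def gibbs_sweep(state: GibbsState, design: GibbsDesign,
                rng: np.random.Generator) -> GibbsState:
    """One full-conditional update of (latents | rest), (b | rest),
    (beta | rest), (Sigma_b | rest). Mutates and returns `state`."""
    r1, r2 = design.r1, design.r2
    J = len(design.cluster_ids)
    Sig = state.Sigma_b
    s11 = Sig[:r1, :r1]
    s12 = Sig[:r1, r1:]
    s22 = Sig[r1:, r1:]

    # --- level-1 latents, truncated by the observed category
    mean1 = design.X1 @ state.beta1 + state.b1[design.cl_idx]
    side1 = np.where(np.isnan(design.y1), 0, np.where(design.y1 > 0, 1, -1))
    state.lat1 = _rtruncnorm(rng, mean1, 1.0, side1)

    # --- clinician effects on level-1 latents, conditional on b2
    b2 = state.b2(design)
    s22i = np.linalg.inv(s22)
    cond_mean = b2 @ (s22i @ s12.T)           # (J, r1)
    cond_cov = s11 - s12 @ s22i @ s12.T if r2 else s11
    vc_inv = np.linalg.inv(cond_cov)
    resid_sum = np.add.reduceat(state.lat1 - design.X1 @ state.beta1,
                                design.starts, axis=0)
    prec = vc_inv[None, :, :] + np.eye(r1)[None, :, :] * design.n_j[:, None, None]
    rhs = (cond_mean @ vc_inv.T) + resid_sum
    cov_j = np.linalg.inv(prec)
    mean_j = np.einsum("jab,jb->ja", cov_j, rhs)
    chol_j = np.linalg.cholesky(cov_j + 1e-12 * np.eye(r1)[None])
    state.b1 = mean_j + np.einsum("jab,jb->ja", chol_j,
                                  rng.standard_normal((J, r1)))

    # --- level-2 latents (equivalently b2), one target at a time
    eta2 = design.X2 @ state.beta2
    side2 = np.where(np.isnan(design.y2), 0, np.where(design.y2 > 0, 1, -1))
    d = r1 + r2
    bfull = np.concatenate([state.b1, state.lat2 - eta2], axis=1)
    for u in range(r2):
        iu = r1 + u
        others = [i for i in range(d) if i != iu]
        so = Sig[np.ix_(others, others)]
        su = Sig[iu, others]
        w = np.linalg.solve(so, su)
        cmean = bfull[:, others] @ w
        cvar = float(Sig[iu, iu] - su @ w)
        cvar = max(cvar, 1e-10)
        draw = _rtruncnorm(rng, eta2[:, u] + cmean, np.sqrt(cvar),
                           side2[:, u])
        state.lat2[:, u] = draw
        bfull[:, iu] = draw - eta2[:, u]

    # --- regression coefficients
    xtx1 = design.X1.T @ design.X1
    xtx1_inv = np.linalg.pinv(xtx1, rcond=1e-10)
    z1 = state.lat1 - state.b1[design.cl_idx]
    bhat1 = xtx1_inv @ (design.X1.T @ z1)
    c1 = _psd_sqrt(xtx1_inv)
    state.beta1 = bhat1 + c1 @ rng.standard_normal(bhat1.shape)

    # beta2: GLS with the conditional covariance of b2 given b1
    s11i = np.linalg.inv(s11)
    m2 = state.b1 @ (s11i @ s12)              # (J, r2)
    vc2 = s22 - s12.T @ s11i @ s12
    vc2 = (vc2 + vc2.T) / 2.0 + 1e-10 * np.eye(r2)
    z2 = state.lat2 - m2
    xtx2_inv = np.linalg.pinv(design.X2.T @ design.X2, rcond=1e-10)
    bhat2 = xtx2_inv @ (design.X2.T @ z2)
    cl_ = _psd_sqrt(xtx2_inv)
    cr = _psd_sqrt(vc2)
    noise = rng.standard_normal(bhat2.shape)
    state.beta2 = bhat2 + cl_ @ noise @ cr.T

    # --- random-effect covariance: inverse-Wishart full conditional
    # (b2 is the level-2 latent residual under the refreshed beta2)
    ball = np.concatenate([state.b1, state.b2(design)], axis=1)
    scale = np.eye(d) + ball.T @ ball
    df = d + J
    for attempt in range(3):
        draw = invwishart.rvs(df=df, scale=scale, random_state=rng)
        draw = np.atleast_2d(draw)
        try:
            np.linalg.cholesky(draw)
            break
        except np.linalg.LinAlgError:  # resample with jitter
            scale = scale + 1e-8 * np.eye(d)
    state.Sigma_b = (draw + draw.T) / 2.0
    return state


def _trace_row(state: GibbsState, design: GibbsDesign) -> dict:
    row = {}
    for t, name in enumerate(design.names1):
        for q in range(state.beta1.shape[0]):
            row[f"beta1_{name}_{q}"] = state.beta1[q, t]
    for t, name in enumerate(design.names2):
        for q in range(state.beta2.shape[0]):
            row[f"beta2_{name}_{q}"] = state.beta2[q, t]
    d = state.Sigma_b.shape[0]
    for i in range(d):
        for j in range(i + 1):
            row[f"sigma_b_{i}{j}"] = state.Sigma_b[i, j]
    return row


def _complete(data: TrialDataset, design: GibbsDesign, spec: ImputationSpec,
              state: GibbsState) -> TrialDataset:
    out = data.copy()
    df = out.df
    inv = np.empty_like(design.order)
    inv[design.order] = np.arange(len(design.order))
    for t, name in enumerate(design.names1):
        col = df[name].to_numpy(float).copy()
        miss = np.isnan(col)
        imputed_sorted = (state.lat1[:, t] >= 0).astype(float)
        col[miss] = imputed_sorted[inv][miss]
        df[name] = col
    cl_of_row = df["clinician_id"].to_numpy(float)
    for t, name in enumerate(design.names2):
        col = df[name].to_numpy(float).copy()
        miss = np.isnan(col)
        imputed_j = (state.lat2[:, t] >= 0).astype(float)
        j_of_row = np.searchsorted(design.cluster_ids, cl_of_row)
        col[miss] = imputed_j[j_of_row][miss]
        df[name] = col
    return out


def run_imputation(data: TrialDataset, spec: ImputationSpec) -> ImputedStack:
    """Gibbs-sample the latent-normal model and save M completed datasets at
    iterations burn_in, burn_in + between, ..., burn_in + (M-1) * between.
    Observed cells are never altered."""
    targets = list(spec.level1_targets) + list(spec.level2_targets)
    any_missing = any(data.df[t].isna().any() for t in targets)
    if not any_missing:
        return ImputedStack(datasets=[data.copy() for _ in range(spec.M)],
                            trace=pd.DataFrame())

    design = build_gibbs_design(data, spec)
    state = init_state(design)
    rng = np.random.default_rng(spec.seed)
    total = spec.burn_in + (spec.M - 1) * spec.between
    save_at = {spec.burn_in + m * spec.between: m for m in range(spec.M)}
    datasets: list[TrialDataset | None] = [None] * spec.M
    trace_rows = []
    for sweep in range(1, total + 1):
        state = gibbs_sweep(state, design, rng)
        trace_rows.append(_trace_row(state, design))
        if sweep in save_at:
            datasets[save_at[sweep]] = _complete(data, design, spec, state)
    trace = pd.DataFrame(trace_rows)
    trace.insert(0, "sweep", np.arange(1, total + 1))
    return ImputedStack(datasets=datasets, trace=trace)


def convergence_report(stack: ImputedStack) -> pd.DataFrame:
    """Per-parameter trace diagnostics: mean, lag-1 autocorrelation, and a
    first-half/second-half drift flag. Diagnostic only, no pass/fail."""
    trace = stack.trace
    if trace.empty:
        raise ValueError("trace is empty (nothing was imputed)")
    rows = []
    for col in [c for c in trace.columns if c != "sweep"]:
        x = trace[col].to_numpy(float)
        T = len(x)
        sd = x.std()
        if sd < 1e-14:
            rows.append({"parameter": col, "mean": x.mean(),
                         "lag1_autocorr": np.nan, "flag": "constant"})
            continue
        lag1 = float(np.corrcoef(x[:-1], x[1:])[0, 1])
        half = T // 2
        drift = abs(x[:half].mean() - x[half:].mean())
        # half-mean standard error inflated for AR(1)-style autocorrelation
        r = min(max(lag1, 0.0), 0.95)
        thresh = 2.0 * sd * np.sqrt((1 + r) / (1 - r)) / np.sqrt(half)
        flag = "drift" if drift > thresh else ""
        rows.append({"parameter": col, "mean": float(x.mean()),
                     "lag1_autocorr": lag1, "flag": flag})
    return pd.DataFrame(rows)
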