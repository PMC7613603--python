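"""Synthetic three-level trial data with correlated binary outcomes.

Generates patient records nested in clinicians nested in hospitals, with nine
(or fewer) binary quality-of-care indicators driven by clinician-level random
intercepts that are correlated across indicators, and missing-at-random
missingness in patient sex, clinician sex and clinician cadre. The default
configuration emulates the pneumonia trial that motivates this package:
12 hospitals in two trial arms, about 32 clinicians per hospital, 3--46
patients per clinician, covariate marginals matching the published
descriptives, and the published missingness rates with near-coincident
missingness of the two clinician-level variables.

Outcomes are generated directly as binary indicators on the logit scale;
the underlying clinical coding rules (doses, respiratory rates, ...) are not
simulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import reference
from .design import COEF_LABELS, K, build_design

ID_COLUMNS = ["hospital_id", "clinician_id", "patient_id"]
COVARIATE_COLUMNS = [
    "time_months", "arm", "malaria", "workload",
    "cadre", "clin_sex", "age_group", "pat_sex", "comorbid",
]
MISSABLE = ["pat_sex", "clin_sex", "cadre"]
CLINICIAN_LEVEL = {"clin_sex", "cadre"}


def outcome_columns(p: int) -> list[str]:
    return [f"y{r}" for r in range(1, p + 1)]


@dataclass
class MissingSpec:
    """Missingness mechanism for one covariate.

    `mechanism` is "MCAR" or "MAR"; under MAR the missingness probability is
    a logistic function of the (fully observed) `predictors` with the given
    log-odds `slopes`, with the intercept calibrated so the marginal rate
    equals `rate`. `couple_with` ties this variable's missingness to another
    already-processed variable: with probability `coupling` a unit missing
    the coupled variable is missing this one too.
    """

    variable: str
    rate: float
    mechanism: str = "MCAR"
    predictors: tuple[str, ...] = ()
    slopes: tuple[float, ...] = ()
    couple_with: str | None = None
    coupling: float = 0.95

    def __post_init__(self):
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"missingness rate {self.rate} outside [0, 1]")
        if self.variable not in MISSABLE:
            raise ValueError(f"missingness not supported for {self.variable!r}")
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if len(self.predictors) != len(self.slopes):
            raise ValueError("predictors and slopes must have equal length")


@dataclass
class GeneratorParams:
    """Configuration of the synthetic trial generator.

    `beta` is the p x 13 matrix of fixed effects on the log-odds scale (one
    row per outcome, columns in `design.COEF_LABELS` order); `D_true` the
    p x p covariance of the clinician random intercepts (log-odds^2).
    `clinicians_per_hospital` is (mean, dispersion) of a shifted negative
    binomial (minimum 1); `patients_per_clinician` is (mean, dispersion,
    low, high) truncated to [low, high].
    """

    beta: np.ndarray
    D_true: np.ndarray
    n_hospitals: int = 12
    intervention_prop: float = 0.5
    clinicians_per_hospital: tuple[float, float] = (32.0, 8.0)
    patients_per_clinician: tuple[float, float, int, int] = (5.6, 2.0, 3, 46)
    follow_up_months: tuple[float, float] = (0.0, 8.0)
    covariate_probs: dict = field(default_factory=lambda: default_covariate_probs())
    missingness: list[MissingSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.D_true = np.asarray(self.D_true, dtype=float)
        p = self.beta.shape[0]
        if self.beta.shape[1] != K:
            raise ValueError(
                f"beta must have {K} columns (one per design term), "
                f"got {self.beta.shape[1]}"
            )
        if self.D_true.shape != (p, p):
            raise ValueError("D_true shape must match the number of outcomes")
        if not np.allclose(self.D_true, self.D_true.T, atol=1e-10):
            raise ValueError("D_true must be symmetric")
        w = np.linalg.eigvalsh(self.D_true)
        if w.min() < -1e-8:
            raise ValueError(
                "D_true is not positive semidefinite "
                f"(smallest eigenvalue {w.min():.4g})"
            )

    @property
    def p(self) -> int:
        return self.beta.shape[0]


@dataclass
class TrialDataset:
    """Patient-level records with hospital/clinician hierarchy and p binary
    outcomes. Missing covariate cells are NaN; outcomes are never missing."""

    df: pd.DataFrame
    p: int

    @property
    def n_patients(self) -> int:
        return len(self.df)

    @property
    def n_clinicians(self) -> int:
        return int(self.df["clinician_id"].dropna().nunique())

    @property
    def n_hospitals(self) -> int:
        return int(self.df["hospital_id"].nunique())

    def outcome_matrix(self) -> np.ndarray:
        return self.df[outcome_columns(self.p)].to_numpy(float)

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.df.copy(), self.p)

    def clinician_table(self) -> pd.DataFrame:
        """One row per clinician with the clinician/hospital-level columns."""
        cols = ["clinician_id", "hospital_id", "arm", "malaria", "workload",
                "cadre", "clin_sex"]
        sub = self.df.dropna(subset=["clinician_id"])
        return sub[cols].groupby("clinician_id", as_index=False).first()

    def validate(self, allow_missing_clinician: bool = False) -> None:
        df = self.df
        ycols = outcome_columns(self.p)
        for c in ID_COLUMNS + COVARIATE_COLUMNS + ycols:
            if c not in df.columns:
                raise ValueError(f"missing column {c!r}")
        y = df[ycols].to_numpy(float)
        if np.isnan(y).any():
            raise ValueError("outcomes must never be missing")
        if not np.isin(y, (0.0, 1.0)).all():
            bad = np.unique(y[~np.isin(y, (0.0, 1.0))])
            raise ValueError(f"non-binary outcome values {bad}")
        if not allow_missing_clinician and df["clinician_id"].isna().any():
            raise ValueError(
                "rows lack a clinician id; run exclude_missing_cluster first"
            )
        for c in ["hospital_id", "patient_id", "time_months", "arm", "malaria",
                  "workload", "age_group", "comorbid"]:
            if df[c].isna().any():
                raise ValueError(f"column {c!r} may not contain missing values")
        # hierarchy referential integrity
        sub = df.dropna(subset=["clinician_id"])
        per_clin = sub.groupby("clinician_id")["hospital_id"].nunique()
        if (per_clin > 1).any():
            bad = per_clin[per_clin > 1].index.tolist()
            raise ValueError(f"clinicians mapped to multiple hospitals: {bad}")
        if df["patient_id"].duplicated().any():
            raise ValueError("duplicate patient ids")


def default_covariate_probs() -> dict:
    r = reference
    return {
        "age_2_11": r.AGE_2_11_MONTHS[0] / r.AGE_2_11_MONTHS[1],
        "patient_male": r.PATIENT_MALE[0] / r.PATIENT_MALE[1],
        "comorbid": tuple(c / sum(r.COMORBIDITY_COUNTS)
                          for c in r.COMORBIDITY_COUNTS),
        "cadre_co": r.CADRE_CLINICAL_OFFICER[0] / r.CADRE_CLINICAL_OFFICER[1],
        "clinician_female": r.CLINICIAN_FEMALE[0] / r.CLINICIAN_FEMALE[1],
        "high_malaria": r.HIGH_MALARIA_HOSPITALS[0] / r.HIGH_MALARIA_HOSPITALS[1],
        "high_workload": 0.5,
    }


# Marginal prevalence targets used by the default configuration. Printed rates
# where available; the unprinted assessment indicators (cough, difficult
# breathing, AVPU, indrawing) are set to high values consistent with the
# trial's description of them as well documented.
DEFAULT_PREVALENCES = {
    "cough": 0.97,
    "difficult_breathing": 0.95,
    "respiratory_rate": reference.DOC_COUNTS["respiratory_rate"][0] / 2127,
    "oxygen_saturation": reference.DOC_COUNTS["oxygen_saturation"][0] / 2127,
    "avpu": 0.80,
    "indrawing": 0.85,
    "correct_diagnosis": reference.DOC_COUNTS["correct_diagnosis"][0] / 2127,
    "correct_treatment": reference.DOC_COUNTS["correct_treatment"][0] / 2127,
    "correct_dose": reference.DOC_COUNTS["correct_dose"][0] / 2127,
}

# Non-intercept effects (log-odds) shared across outcomes in the default
# configuration; the time-by-arm interaction is positive for the six
# indicators reported to improve under enhanced audit-and-feedback.
_DEFAULT_SLOPES = {
    "age_2_11mo": -0.2,
    "patient_male": 0.0,
    "comorbid_0": 0.3,
    "comorbid_1": 0.2,
    "comorbid_2": 0.1,
    "cadre_co": 0.25,
    "clinician_female": -0.2,
    "high_workload": -0.3,
    "high_malaria": 0.2,
    "time_months": 0.02,
    "arm": 0.1,
}
_IMPROVING = {"respiratory_rate", "oxygen_saturation", "indrawing",
              "correct_diagnosis", "correct_treatment", "correct_dose"}


def nearest_psd(m: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped projection onto the PSD cone (symmetrized)."""
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    return (v * np.maximum(w, floor)) @ v.T


def calibrate_intercept(target: float, offsets: np.ndarray, sigma2_b: float,
                        n_quad: int = 21) -> float:
    """Intercept giving marginal prevalence `target` when the linear predictor
    is intercept + offsets + b, b ~ N(0, sigma2_b), averaging over the
    empirical offset sample and the random intercept by Gauss-Hermite."""
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    bs = np.sqrt(2.0 * max(sigma2_b, 0.0)) * z
    wn = w / np.sqrt(np.pi)

    def f(b0):
        return np.mean(expit(b0 + offsets[:, None] + bs[None, :]) @ wn) - target

    return brentq(f, -15.0, 15.0, xtol=1e-10)


def _covariate_sample(n: int, probs: dict, follow_up: tuple[float, float],
                      rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = follow_up
    return pd.DataFrame({
        "time_months": rng.uniform(lo, hi, n),
        "arm": rng.random(n) < 0.5,
        "malaria": rng.random(n) < probs["high_malaria"],
        "workload": rng.random(n) < probs["high_workload"],
        "cadre": rng.random(n) < probs["cadre_co"],
        "clin_sex": rng.random(n) < probs["clinician_female"],
        "age_group": rng.random(n) < probs["age_2_11"],
        "pat_sex": rng.random(n) < probs["patient_male"],
        "comorbid": rng.choice(4, size=n, p=probs["comorbid"]),
    }).astype(float)


def default_beta(p: int = 9, D: np.ndarray | None = None,
                 probs: dict | None = None,
                 prevalences: dict | None = None) -> np.ndarray:
    """Default p x 13 fixed-effects matrix: shared covariate slopes with
    intercepts calibrated so each outcome's marginal prevalence matches its
    target given the covariate marginals and random-intercept variance."""
    probs = probs or default_covariate_probs()
    prevalences = prevalences or DEFAULT_PREVALENCES
    if D is None:
        D = nearest_psd(reference.varcorr_to_cov(reference.VARCORR_MI))[:p, :p]
    names = reference.OUTCOMES[:p]
    rng = np.random.default_rng(987654321)  # internal calibration sample
    sample = _covariate_sample(20_000, probs, (0.0, 8.0), rng)
    beta = np.zeros((p, K))
    for r, name in enumerate(names):
        for j, lab in enumerate(COEF_LABELS):
            if lab == "intercept":
                continue
            if lab == "time_x_arm":
                beta[r, j] = 0.15 if name in _IMPROVING else 0.0
            else:
                beta[r, j] = _DEFAULT_SLOPES[lab]
        x = build_design(sample)
        offsets = x[:, 1:] @ beta[r, 1:]
        beta[r, 0] = calibrate_intercept(prevalences[name], offsets,
                                         float(D[r, r]))
    return beta


def default_missingness() -> list[MissingSpec]:
    r = reference
    return [
        MissingSpec("cadre", r.CADRE_MISSING[0] / r.CADRE_MISSING[1],
                    mechanism="MAR", predictors=("workload",), slopes=(0.5,)),
        MissingSpec("clin_sex", r.CLIN_SEX_MISSING[0] / r.CLIN_SEX_MISSING[1],
                    mechanism="MCAR", couple_with="cadre", coupling=0.95),
        MissingSpec("pat_sex", r.PAT_SEX_MISSING[0] / r.PAT_SEX_MISSING[1],
                    mechanism="MCAR"),
    ]


def default_params(p: int = 9, seed: int = 0, with_missingness: bool = True,
                   prevalences: dict | None = None) -> GeneratorParams:
    """The trial-emulation configuration (12 hospitals, ~378 clinicians,
    ~2127 patients, published covariate marginals and missingness rates)."""
    D = nearest_psd(reference.varcorr_to_cov(reference.VARCORR_MI))[:p, :p]
    beta = default_beta(p, D=D, prevalences=prevalences)
    return GeneratorParams(
        beta=beta,
        D_true=D,
        missingness=default_missingness() if with_missingness else [],
        seed=seed,
    )


def desk_params(p: int = 3, seed: int = 0, n_hospitals: int = 6,
                clinicians_per_hospital: tuple[float, float] = (10.0, 8.0),
                patients_per_clinician: tuple[float, float, int, int] = (6.0, 2.0, 3, 46),
                with_missingness: bool = True) -> GeneratorParams:
    """A small configuration (default ~60 clinicians) for bounded-time runs.

    Outcome prevalences are kept moderate so that the 13-term design stays
    identifiable at a few hundred patients (the near-one documentation rates
    of the full-scale configuration would separate at this sample size).
    """
    moderate = [0.65, 0.5, 0.4, 0.6, 0.45, 0.55, 0.5, 0.6, 0.35]
    prevalences = {name: moderate[i % len(moderate)]
                   for i, name in enumerate(reference.OUTCOMES)}
    base = default_params(p=p, seed=seed, with_missingness=with_missingness,
                          prevalences=prevalences)
    return dataclasses.replace(
        base,
        n_hospitals=n_hospitals,
        clinicians_per_hospital=clinicians_per_hospital,
        patients_per_clinician=patients_per_clinician,
    )


def _shifted_negbin(rng, n, mean, dispersion, minimum, maximum=None):
    extra = max(mean - minimum, 0.01)
    prob = dispersion / (dispersion + extra)
    draws = minimum + rng.negative_binomial(dispersion, prob, size=n)
    if maximum is not None:
        draws = np.minimum(draws, maximum)
    return draws


def _mvn_psd(rng, cov, size):
    w, v = np.linalg.eigh((cov + cov.T) / 2.0)
    root = v * np.sqrt(np.maximum(w, 0.0))
    z = rng.standard_normal((size, cov.shape[0]))
    return z @ root.T


def generate(params: GeneratorParams, seed: int | None = None) -> TrialDataset:
    """Draw a complete synthetic trial dataset, then apply the configured
    missingness. One random-intercept vector b_j ~ MVN(0, D_true) is drawn
    per clinician and shared by all of that clinician's patients; outcome r
    for a patient is Bernoulli(logit^{-1}(x'beta_r + b_{j,r}))."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    p = params.p
    probs = params.covariate_probs

    nh = params.n_hospitals
    n_int = int(round(nh * params.intervention_prop))
    arm_h = rng.permutation(np.r_[np.ones(n_int), np.zeros(nh - n_int)])
    n_mal = int(round(nh * probs["high_malaria"]))
    malaria_h = rng.permutation(np.r_[np.ones(n_mal), np.zeros(nh - n_mal)])
    n_wl = int(round(nh * probs["high_workload"]))
    workload_h = rng.permutation(np.r_[np.ones(n_wl), np.zeros(nh - n_wl)])

    cm, cd = params.clinicians_per_hospital
    n_clin_h = _shifted_negbin(rng, nh, cm, cd, 1)
    j_total = int(n_clin_h.sum())
    clin_hospital = np.repeat(np.arange(1, nh + 1), n_clin_h)
    cadre_j = (rng.random(j_total) < probs["cadre_co"]).astype(float)
    sex_j = (rng.random(j_total) < probs["clinician_female"]).astype(float)

    pm, pd_, lo, hi = params.patients_per_clinician
    n_pat_j = _shifted_negbin(rng, j_total, pm, pd_, lo, hi)
    n = int(n_pat_j.sum())
    pat_clin = np.repeat(np.arange(1, j_total + 1), n_pat_j)

    b = _mvn_psd(rng, params.D_true, j_total)

    t0, t1 = params.follow_up_months
    df = pd.DataFrame({
        "hospital_id": clin_hospital[pat_clin - 1].astype(np.int64),
        "clinician_id": pat_clin.astype(np.int64),
        "patient_id": np.arange(1, n + 1, dtype=np.int64),
        "time_months": rng.uniform(t0, t1, n),
        "arm": arm_h[clin_hospital[pat_clin - 1] - 1],
        "malaria": malaria_h[clin_hospital[pat_clin - 1] - 1],
        "workload": workload_h[clin_hospital[pat_clin - 1] - 1],
        "cadre": cadre_j[pat_clin - 1],
        "clin_sex": sex_j[pat_clin - 1],
        "age_group": (rng.random(n) < probs["age_2_11"]).astype(float),
        "pat_sex": (rng.random(n) < probs["patient_male"]).astype(float),
        "comorbid": rng.choice(4, size=n, p=probs["comorbid"]).astype(float),
    })
    df["clinician_id"] = df["clinician_id"].astype("Int64")

    x = build_design(df, check_rank=False)
    eta = x @ params.beta.T + b[pat_clin - 1]
    y = (rng.random((n, p)) < expit(eta)).astype(np.int64)
    for r in range(p):
        df[f"y{r + 1}"] = y[:, r]

    data = TrialDataset(df, p)
    if params.missingness:
        sub_seed = int(rng.integers(2 ** 31))
        data = impose_missingness(data, params.missingness, seed=sub_seed)
    return data


def _calibrated_mar_prob(xmat: np.ndarray, slopes: np.ndarray,
                         rate: float) -> np.ndarray:
    eta0 = xmat @ slopes

    def f(alpha):
        return float(np.mean(expit(alpha + eta0)) - rate)

    alpha = brentq(f, -20.0, 20.0, xtol=1e-10)
    return expit(alpha + eta0)


def impose_missingness(data: TrialDataset, specs: list[MissingSpec],
                       seed: int = 0) -> TrialDataset:
    """Blank covariate cells according to `specs` (clinician-level variables
    are blanked per clinician and propagated to all their rows)."""
    rng = np.random.default_rng(seed)
    out = data.copy()
    df = out.df
    processed: dict[str, np.ndarray] = {}

    for spec in specs:
        if spec.variable in CLINICIAN_LEVEL:
            units = data.clinician_table()
        else:
            units = df
        m = len(units)
        for pred in spec.predictors:
            if units[pred].isna().any():
                raise ValueError(
                    f"MAR predictor {pred!r} has missing values; the "
                    "mechanism would not be missing-at-random"
                )
        if spec.rate == 0 and spec.couple_with is None:
            continue
        if spec.mechanism == "MAR" and spec.predictors:
            xmat = units[list(spec.predictors)].to_numpy(float)
            prob = _calibrated_mar_prob(xmat, np.asarray(spec.slopes), spec.rate)
        else:
            prob = np.full(m, spec.rate)
        if spec.couple_with is not None:
            if spec.couple_with not in processed:
                raise ValueError(
                    f"{spec.variable!r} is coupled to {spec.couple_with!r}, "
                    "which must be listed earlier"
                )
            cm = processed[spec.couple_with]
            rate_c = float(cm.mean())
            if rate_c < 1.0:
                resid = (spec.rate - spec.coupling * rate_c) / (1.0 - rate_c)
            else:
                resid = 0.0
            resid = float(np.clip(resid, 0.0, 1.0))
            prob = np.where(cm, spec.coupling, resid)
        miss = rng.random(m) < prob
        processed[spec.variable] = miss
        if spec.variable in CLINICIAN_LEVEL:
            miss_ids = set(units.loc[miss, "clinician_id"].tolist())
            row_mask = df["clinician_id"].isin(miss_ids).to_numpy()
        else:
            row_mask = miss
        df.loc[row_mask, spec.variable] = np.nan
    return out


def exclude_missing_cluster(data: TrialDataset):
    """Drop rows lacking a clinician identifier; returns the filtered dataset
    and a report with count, total and percentage to one decimal."""
    df = data.df
    lacking = df["clinician_id"].isna()
    kept = TrialDataset(df.loc[~lacking].reset_index(drop=True), data.p)
    n_total = len(df)
    n_exc = int(lacking.sum())
    pct = round(100.0 * n_exc / n_total, 1) if n_total else 0.0
    report = {
        "excluded": n_exc,
        "total": n_total,
        "retained": n_total - n_exc,
        "pct": pct,
        "summary": f"{n_exc}/{n_total} ({pct}%)",
    }
    return kept, report


def drop_clinician_ids(data: TrialDataset, n_missing: int,
                       seed: int = 0) -> TrialDataset:
    """Blank the clinician id on `n_missing` randomly chosen rows (emulating
    admissions whose clinician was never recorded)."""
    rng = np.random.default_rng(seed)
    out = data.copy()
    idx = rng.choice(len(out.df), size=n_missing, replace=False)
    col = out.df["clinician_id"].astype("Int64").copy()
    col.iloc[idx] = pd.NA
    out.df["clinician_id"] = col
    return out


def write_csv(data: TrialDataset, path) -> None:
    """Fixed-layout CSV, one row per patient; missing cells are empty fields.
    Boolean missing-indicator columns are appended for auditability."""
    df = data.df.copy()
    for v in MISSABLE:
        df[f"miss_{v}"] = df[v].isna().astype(np.int64)
    cols = (ID_COLUMNS + COVARIATE_COLUMNS + outcome_columns(data.p)
            + [f"miss_{v}" for v in MISSABLE])
    df[cols].to_csv(path, index=False, na_rep="")


def read_csv(path) -> TrialDataset:
    """Read the layout written by `write_csv`, validating the schema.

    Rows lacking a clinician id are accepted and flagged for
    `exclude_missing_cluster`; any other schema violation raises ValueError.
    """
    df = pd.read_csv(path, na_values=[""], keep_default_na=False)
    ycols = sorted([c for c in df.columns if c.startswith("y") and c[1:].isdigit()],
                   key=lambda c: int(c[1:]))
    p = len(ycols)
    if p == 0 or ycols != outcome_columns(p):
        raise ValueError(f"outcome columns must be y1..yp, found {ycols}")
    expected = set(ID_COLUMNS + COVARIATE_COLUMNS + ycols
                   + [f"miss_{v}" for v in MISSABLE])
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ValueError(f"unknown columns {unknown}")
    missing_cols = [c for c in ID_COLUMNS + COVARIATE_COLUMNS + ycols
                    if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns {missing_cols}")
    y = df[ycols].to_numpy(float)
    bad_rows = np.where(~np.isin(y, (0.0, 1.0)).all(axis=1))[0]
    if len(bad_rows):
        raise ValueError(
            f"non-binary outcome values in rows {bad_rows.tolist()[:20]}"
        )
    df = df.drop(columns=[c for c in df.columns if c.startswith("miss_")])
    df["clinician_id"] = df["clinician_id"].astype("Int64")
    for c in ["hospital_id", "patient_id"] + ycols:
        df[c] = df[c].astype(np.int64)
    for c in COVARIATE_COLUMNS:
        df[c] = df[c].astype(float)
    data = TrialDataset(df, p)
    data.validate(allow_missing_clinician=True)
    return data


def datasets_equal(a: TrialDataset, b: TrialDataset) -> bool:
    if a.p != b.p or len(a.df) != len(b.df):
        return False
    cols = ID_COLUMNS + COVARIATE_COLUMNS + outcome_columns(a.p)
    da, db = a.df[cols], b.df[cols]
    for c in cols:
        xa, xb = da[c].to_numpy(float), db[c].to_numpy(float)
        if not np.array_equal(np.isnan(xa), np.isnan(xb)):
            return False
        ok = np.isnan(xa) | np.isclose(xa, xb, rtol=0, atol=1e-12)
        if not ok.all():
            return False
    return True
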