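"""Fixed-effects design for the quality-of-care regressions.

Every outcome shares one 13-term linear predictor: an intercept plus patient-,
clinician- and hospital-level covariates, calendar time, trial arm and the
time-by-arm interaction. Comorbidity count (0/1/2/3+) enters through three
indicator contrasts against the ">= 3 comorbidities" reference category.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# Canonical coefficient order. The time-by-arm interaction is deliberately the
# last term so that it occupies position k within each outcome's block.
COEF_LABELS = [
    "intercept",
    "age_2_11mo",
    "patient_male",
    "comorbid_0",
    "comorbid_1",
    "comorbid_2",
    "cadre_co",
    "clinician_female",
    "high_workload",
    "high_malaria",
    "time_months",
    "arm",
    "time_x_arm",
]

K = len(COEF_LABELS)

_COLUMN_OF = {
    "age_2_11mo": "age_group",
    "patient_male": "pat_sex",
    "cadre_co": "cadre",
    "clinician_female": "clin_sex",
    "high_workload": "workload",
    "high_malaria": "malaria",
    "time_months": "time_months",
    "arm": "arm",
}


def term_column(df: pd.DataFrame, label: str) -> np.ndarray:
    if label == "intercept":
        return np.ones(len(df))
    if label == "time_x_arm":
        return df["time_months"].to_numpy(float) * df["arm"].to_numpy(float)
    if label.startswith("comorbid_"):
        level = int(label.split("_")[1])
        return (df["comorbid"].to_numpy(float) == level).astype(float)
    return df[_COLUMN_OF[label]].to_numpy(float)


def build_design(df: pd.DataFrame, terms: list[str] | None = None,
                 check_rank: bool = True) -> np.ndarray:
    """Design matrix (n x k) in the order of `terms` (default: all 13).

    Raises ValueError if any required covariate is missing (models are fitted
    on complete or completed data only) or, when `check_rank`, the matrix is
    column-rank deficient. Rank is irrelevant when the matrix is only used
    to evaluate linear predictors (e.g. while simulating outcomes).
    """
    terms = list(terms) if terms is not None else list(COEF_LABELS)
    unknown = [t for t in terms if t != "intercept" and t != "time_x_arm"
               and not t.startswith("comorbid_") and t not in _COLUMN_OF]
    if unknown:
        raise ValueError(f"unknown design terms: {unknown}")
    cols = []
    for t in terms:
        col = term_column(df, t)
        if np.isnan(col).any():
            raise ValueError(
                f"design term {t!r} has missing values; fit on complete "
                "or imputed data"
            )
        cols.append(col)
    x = np.column_stack(cols)
    if check_rank and np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient for these data")
    return x
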