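"""Published summary quantities from the motivating pneumonia-care trial.

The trial enrolled children (2--59 months) admitted with pneumonia to 12
Kenyan hospitals randomized to enhanced versus standard audit-and-feedback.
Its raw records are not publicly available, so the quantities below -- the
printed count/denominator pairs, covariate marginals, and the reported
variance--correlation matrices of the clinician-level random intercepts --
are the reference inputs this package uses both to parameterize its
synthetic-data generator and to recompute the reported summary statistics.

All matrices are ordered by the nine care indicators::

    y1 cough, y2 difficult breathing, y3 respiratory rate,
    y4 oxygen saturation, y5 AVPU, y6 chest-wall indrawing,
    y7 correct diagnosis, y8 amoxicillin prescription, y9 correct dose
"""

from __future__ import annotations

import numpy as np

OUTCOMES = [
    "cough",
    "difficult_breathing",
    "respiratory_rate",
    "oxygen_saturation",
    "avpu",
    "indrawing",
    "correct_diagnosis",
    "correct_treatment",
    "correct_dose",
]

# (count, denominator) pairs as published
EXCLUDED_RECORDS = (172, 2299)          # admissions lacking clinician information
CLIN_SEX_MISSING = (83, 378)            # clinicians with missing gender
CADRE_MISSING = (82, 378)               # clinicians with missing cadre
PAT_SEX_MISSING = (17, 2127)            # case records with missing patient gender
INTERVENTION_PATIENTS = (953, 2127)     # admissions in the six intervention hospitals

# Documentation / adherence rates for the indicators that were printed.
DOC_COUNTS = {
    "respiratory_rate": (1889, 2127),
    "oxygen_saturation": (1297, 2127),
    "correct_diagnosis": (1473, 2127),
    "correct_treatment": (1036, 2127),
    "correct_dose": (523, 2127),
}

# Covariate marginals
AGE_2_11_MONTHS = (903, 2127)
PATIENT_MALE = (1164, 2114)             # among patients with observed gender
COMORBIDITY_COUNTS = (995, 633, 381, 118)   # 0 / 1 / 2 / >=3 of 2127
CLINICIAN_FEMALE = (128, 296)           # among clinicians with observed gender
CADRE_CLINICAL_OFFICER = (190, 295)     # CO + CO-intern, after collapsing to 2 cadres
HIGH_MALARIA_HOSPITALS = (5, 12)

MEAN_CLINICIANS_PER_HOSPITAL = 32
PATIENTS_PER_CLINICIAN_RANGE = (3, 46)
FOLLOW_UP_MONTHS = 8.0                  # trial ran March--November 2016


def _varcorr(diag, lower):
    """Build a symmetric matrix with `diag` on the diagonal and `lower`
    filling the strict lower triangle row by row (mirrored above)."""
    p = len(diag)
    m = np.diag(np.asarray(diag, dtype=float))
    k = 0
    for i in range(1, p):
        for j in range(i):
            m[i, j] = m[j, i] = lower[k]
            k += 1
    if k != len(lower):
        raise ValueError("lower triangle length mismatch")
    return m


# Reported variance-correlation matrices for the clinician random intercepts:
# variances on the diagonal, pairwise correlations below it.
VARCORR_CCA = _varcorr(
    [1.49, 1.92, 2.71, 7.38, 2.26, 2.33, 2.64, 1.81, 1.30],
    [0.07,
     -0.29, -0.43,
     -0.17, -0.47, 0.63,
     -0.14, -0.19, -0.20, 0.09,
     -0.22, -0.11, -0.54, -0.39, -0.19,
     -0.49, -0.53, 0.48, 0.29, -0.06, 0.04,
     -0.48, -0.42, 0.07, 0.16, -0.38, 0.66, 0.64,
     -0.54, -0.64, 0.57, 0.69, -0.21, 0.19, 0.62, 0.73],
)

VARCORR_MI = _varcorr(
    [1.05, 0.71, 2.47, 2.23, 1.76, 1.82, 2.14, 0.56, 0.67],
    [0.17,
     -0.29, -0.60,
     -0.30, -0.78, 0.89,
     -0.12, -0.24, -0.12, 0.22,
     -0.30, 0.06, -0.52, -0.50, -0.26,
     -0.54, -0.65, 0.40, 0.24, -0.07, 0.35,
     -0.45, -0.55, 0.23, 0.26, -0.22, 0.52, 0.77,
     -0.47, -0.76, 0.63, 0.64, -0.18, 0.15, 0.74, 0.80],
)

# Reported first/second principal-component percentages (see association module
# for the PCA convention that reproduces them from the matrices above).
PCA_PCT_CCA = (57.6, 24.6)
PCA_PCT_MI = (60.3, 26.2)


def varcorr_to_corr(vc: np.ndarray) -> np.ndarray:
    """Correlation matrix (unit diagonal) from a variance-correlation table."""
    c = np.array(vc, dtype=float)
    np.fill_diagonal(c, 1.0)
    return c


def varcorr_to_cov(vc: np.ndarray) -> np.ndarray:
    """Covariance matrix implied by a variance-correlation table."""
    v = np.diag(vc)
    c = varcorr_to_corr(vc)
    return c * np.sqrt(np.outer(v, v))


def pct(pair: tuple[int, int], decimals: int = 1) -> float:
    """Percentage from a (count, denominator) pair, rounded half-up to the
    printed precision (69.25 -> 69.3, matching how the rates appear)."""
    import decimal

    count, denom = pair
    q = decimal.Decimal(10) ** -decimals
    d = decimal.Decimal(100 * count) / decimal.Decimal(denom)
    return float(d.quantize(q, rounding=decimal.ROUND_HALF_UP))
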