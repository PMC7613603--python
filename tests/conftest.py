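import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from pairjm.datasets import TrialDataset
from pairjm.design import build_design

SMALL_TERMS = ["intercept", "time_months", "arm", "time_x_arm"]


def simulate_clustered(n_clusters=30, cluster_size=6, p=2, seed=1,
                       D=None, beta=None, terms=None):
    """Balanced clustered binary data from a known logistic random-intercept
    model; returns (dataset, beta_used, D_used). The full covariate frame is
    always populated so any design-term subset can be fitted."""
    rng = np.random.default_rng(seed)
    if D is None:
        D = np.array([[0.8, 0.4, 0.2],
                      [0.4, 1.2, 0.3],
                      [0.2, 0.3, 0.9]])[:p, :p]
    D = np.atleast_2d(D)
    if beta is None:
        beta = rng.normal(0.0, 0.4, (p, 13))
    b = rng.multivariate_normal(np.zeros(p), D, n_clusters)
    rows, pid = [], 0
    for j in range(n_clusters):
        for _ in range(cluster_size):
            pid += 1
            rows.append(dict(
                hospital_id=1 + j % 3, clinician_id=j + 1, patient_id=pid,
                time_months=rng.uniform(0, 8), arm=float(j % 2),
                malaria=float((j // 3) % 2), workload=float((j // 2) % 2),
                cadre=float(rng.random() < 0.6),
                clin_sex=float(rng.random() < 0.4),
                age_group=float(rng.random() < 0.4),
                pat_sex=float(rng.random() < 0.5),
                comorbid=float(rng.integers(0, 4))))
    df = pd.DataFrame(rows)
    X = build_design(df, terms)
    bmat = beta if terms is None else beta[:, :len(terms)]
    eta = X @ bmat.T + b[df["clinician_id"].to_numpy(int) - 1]
    Y = (rng.random((len(df), p)) < expit(eta)).astype(int)
    for r in range(p):
        df[f"y{r + 1}"] = Y[:, r]
    return TrialDataset(df, p), bmat, D


@pytest.fixture(scope="session")
def bivariate_data():
    return simulate_clustered(n_clusters=60, cluster_size=6, p=2, seed=11,
                              terms=SMALL_TERMS,
                              beta=np.array([[0.3, 0.05, 0.2, 0.1] + [0.0] * 9,
                                             [-0.2, 0.1, -0.1, 0.15] + [0.0] * 9]))
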