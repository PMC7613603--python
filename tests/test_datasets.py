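"""Synthetic-data generator: determinism, marginals, missingness mechanisms,
the record-exclusion filter, and CSV round-tripping."""

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

from pairjm import datasets as ds
from pairjm import reference
from pairjm.datasets import (GeneratorParams, MissingSpec, TrialDataset,
                             exclude_missing_cluster, generate,
                             impose_missingness, read_csv, write_csv)
from pairjm.design import K

from conftest import simulate_clustered


def _flat_params(p=1, n_hospitals=4, seed=0, **kw):
    """All-zero fixed effects and no random-effect variance."""
    return GeneratorParams(
        beta=np.zeros((p, K)), D_true=np.zeros((p, p)),
        n_hospitals=n_hospitals, seed=seed,
        clinicians_per_hospital=(10.0, 8.0),
        patients_per_clinician=(8.0, 4.0, 3, 46), **kw)


class TestGenerate:
    def test_seeded_determinism_byte_identical_csv(self):
        params = ds.desk_params(p=3, seed=5)
        a, b = io.StringIO(), io.StringIO()
        write_csv(generate(params), a)
        write_csv(generate(params), b)
        assert a.getvalue() == b.getvalue()

    def test_zero_model_gives_half_prevalence(self):
        # logistic symmetry: beta = 0, D = 0 -> every outcome is a fair coin
        params = _flat_params(p=2, n_hospitals=12, seed=3)
        params = dataclasses.replace(
            params, clinicians_per_hospital=(30.0, 8.0),
            patients_per_clinician=(30.0, 4.0, 3, 60))
        data = generate(params)
        n = data.n_patients
        assert n > 8000
        prev = data.outcome_matrix().mean(axis=0)
        half_width = 3.0 * np.sqrt(0.25 / n)
        assert np.all(np.abs(prev - 0.5) < half_width)

    def test_default_emulation_matches_trial_shape(self):
        data = generate(ds.default_params(seed=1))
        assert data.n_hospitals == 12
        assert 250 < data.n_clinicians < 520
        assert 1400 < data.n_patients < 3000
        ct = data.clinician_table()
        rate = ct["clin_sex"].isna().mean()
        target = reference.CLIN_SEX_MISSING[0] / reference.CLIN_SEX_MISSING[1]
        se = np.sqrt(target * (1 - target) / len(ct))
        assert abs(rate - target) < 3.0 * se

    def test_random_effect_correlation_shows_in_cluster_logits(self):
        rho = 0.8
        D = np.array([[1.0, rho], [rho, 1.0]])
        data, _, _ = simulate_clustered(
            n_clusters=400, cluster_size=50, p=2, seed=21, D=D,
            beta=np.zeros((2, 13)))
        g = data.df.groupby("clinician_id")[["y1", "y2"]].mean()
        logits = np.log(np.clip(g, 0.02, 0.98) /
                        (1 - np.clip(g, 0.02, 0.98)))
        r = np.corrcoef(logits["y1"], logits["y2"])[0, 1]
        assert r > 0.5  # positive and of the right magnitude

        data0, _, _ = simulate_clustered(
            n_clusters=400, cluster_size=50, p=2, seed=21, D=np.eye(2),
            beta=np.zeros((2, 13)))
        g0 = data0.df.groupby("clinician_id")[["y1", "y2"]].mean()
        l0 = np.log(np.clip(g0, 0.02, 0.98) / (1 - np.clip(g0, 0.02, 0.98)))
        assert r > np.corrcoef(l0["y1"], l0["y2"])[0, 1]

    def test_random_effect_covariance_recovery(self):
        D = reference.varcorr_to_cov(reference.VARCORR_MI)[:3, :3]
        rng = np.random.default_rng(7)
        draws = ds._mvn_psd(rng, D, 5000)
        S = np.cov(draws.T)
        # entrywise within 3 Monte-Carlo standard errors
        mcse = np.sqrt((np.outer(np.diag(D), np.diag(D)) + D ** 2) / 5000)
        assert np.all(np.abs(S - D) < 3.0 * mcse)

    def test_non_psd_D_rejected_with_eigenvalue(self):
        D = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="eigenvalue"):
            GeneratorParams(beta=np.zeros((2, K)), D_true=D)

    def test_hierarchy_referential_integrity(self):
        data = generate(ds.desk_params(p=3, seed=2))
        data.validate()
        per_clin = data.df.groupby("clinician_id")["hospital_id"].nunique()
        assert (per_clin == 1).all()


class TestMissingness:
    def test_rate_zero_is_identity(self):
        data = generate(ds.desk_params(p=3, seed=8, with_missingness=False))
        out = impose_missingness(data, [MissingSpec("pat_sex", 0.0)], seed=1)
        assert ds.datasets_equal(data, out)

    def test_patient_sex_rate_near_printed_count(self):
        # 0.7% of ~2127 records -> about 15 missing
        params = ds.default_params(seed=13)
        data = generate(params)
        n = data.n_patients
        rate = reference.PAT_SEX_MISSING[0] / reference.PAT_SEX_MISSING[1]
        n_miss = data.df["pat_sex"].isna().sum()
        assert abs(n_miss - rate * n) < 3.0 * np.sqrt(n * rate * (1 - rate))

    def test_clinician_variables_missing_jointly(self):
        data = generate(ds.default_params(seed=4))
        ct = data.clinician_table()
        cadre_miss = ct["cadre"].isna()
        sex_miss = ct["clin_sex"].isna()
        frac = (sex_miss & cadre_miss).sum() / cadre_miss.sum()
        assert frac >= 0.85  # configured coupling 0.95, binomial noise

    def test_mar_missingness_tracks_predictor(self):
        data = generate(ds.desk_params(p=3, seed=6, with_missingness=False,
                                       n_hospitals=12,
                                       clinicians_per_hospital=(30.0, 8.0)))
        spec = MissingSpec("cadre", 0.3, mechanism="MAR",
                           predictors=("workload",), slopes=(1.0,))
        out = impose_missingness(data, [spec], seed=9)
        ct = out.clinician_table()
        hi = ct.loc[ct.workload == 1, "cadre"].isna().mean()
        lo = ct.loc[ct.workload == 0, "cadre"].isna().mean()
        assert hi > lo
        assert abs(ct["cadre"].isna().mean() - 0.3) < 0.1

    def test_mar_predictor_with_missing_values_rejected(self):
        data = generate(ds.desk_params(p=3, seed=6, with_missingness=False))
        first = impose_missingness(
            data, [MissingSpec("clin_sex", 0.3)], seed=1)
        spec = MissingSpec("cadre", 0.3, mechanism="MAR",
                           predictors=("clin_sex",), slopes=(1.0,))
        with pytest.raises(ValueError, match="missing-at-random"):
            impose_missingness(first, [spec], seed=2)

    def test_realized_rates_within_three_binomial_se(self):
        data = generate(ds.default_params(seed=17))
        ct = data.clinician_table()
        for col, (cnt, den) in [("clin_sex", reference.CLIN_SEX_MISSING),
                                ("cadre", reference.CADRE_MISSING)]:
            target = cnt / den
            se = np.sqrt(target * (1 - target) / len(ct))
            assert abs(ct[col].isna().mean() - target) < 3.0 * se


class TestExclusion:
    def test_printed_exclusion_fraction(self):
        params = ds.default_params(seed=3, with_missingness=False)
        data = generate(params)
        # emulate the admissions whose clinician was never recorded
        n = data.n_patients
        n_missing = int(round(n * reference.EXCLUDED_RECORDS[0]
                              / reference.EXCLUDED_RECORDS[1]))
        broken = ds.drop_clinician_ids(data, n_missing, seed=1)
        kept, rep = exclude_missing_cluster(broken)
        assert rep["excluded"] == n_missing
        assert rep["pct"] == round(100.0 * n_missing / n, 1)
        assert kept.n_patients == n - n_missing
        kept.validate()

    def test_no_missing_ids_is_identity(self):
        data = generate(ds.desk_params(p=3, seed=1))
        kept, rep = exclude_missing_cluster(data)
        assert rep["excluded"] == 0
        assert ds.datasets_equal(kept, data)

    def test_ten_of_hundred(self):
        data = generate(ds.desk_params(
            p=3, seed=5, n_hospitals=4, clinicians_per_hospital=(5.0, 8.0)))
        sub = TrialDataset(data.df.iloc[:100].reset_index(drop=True), 3)
        broken = ds.drop_clinician_ids(sub, 10, seed=2)
        kept, rep = exclude_missing_cluster(broken)
        assert (rep["excluded"], rep["retained"], rep["pct"]) == (10, 90, 10.0)
        assert rep["summary"] == "10/100 (10.0%)"


class TestCsv:
    def test_round_trip_identity(self, tmp_path):
        data = generate(ds.desk_params(p=3, seed=10))
        path = tmp_path / "d.csv"
        write_csv(data, path)
        again = read_csv(path)
        assert ds.datasets_equal(data, again)

    def test_non_binary_outcome_rejected(self, tmp_path):
        data = generate(ds.desk_params(p=3, seed=10, with_missingness=False))
        df = data.df.copy()
        df.loc[4, "y1"] = 2
        path = tmp_path / "bad.csv"
        write_csv(TrialDataset(df, 3), path)
        with pytest.raises(ValueError, match="non-binary"):
            read_csv(path)

    def test_unknown_column_rejected(self, tmp_path):
        data = generate(ds.desk_params(p=3, seed=10))
        path = tmp_path / "d.csv"
        write_csv(data, path)
        df = pd.read_csv(path)
        df["mystery"] = 1
        path2 = tmp_path / "d2.csv"
        df.to_csv(path2, index=False)
        with pytest.raises(ValueError, match="unknown columns"):
            read_csv(path2)

    def test_missing_clinician_ids_read_and_flagged(self, tmp_path):
        data = generate(ds.desk_params(p=3, seed=10))
        broken = ds.drop_clinician_ids(data, 5, seed=3)
        path = tmp_path / "d.csv"
        write_csv(broken, path)
        again = read_csv(path)
        assert again.df["clinician_id"].isna().sum() == 5
        kept, rep = exclude_missing_cluster(again)
        assert rep["excluded"] == 5
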