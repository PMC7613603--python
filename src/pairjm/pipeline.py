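"""End-to-end orchestration: simulate -> exclude -> impute -> pairwise fits
-> combine -> pool -> Wald -> association.

A run writes a deterministic artifact tree under its output directory and a
`run.log` with the content hash of every artifact and every seed actually
used. Completed expensive stages (data, imputations, per-dataset combined
estimates) are reloaded on re-run instead of recomputed.

The complete-case path drops every patient whose model covariates contain a
missing value (losing all patients of clinicians with unrecorded sex or
cadre); the multiple-imputation path analyses each completed dataset and
pools with Rubin's rules.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import datasets as ds
from . import pseudolik as pl
from .design import COEF_LABELS
from .impute import ImputationSpec, run_imputation
from .pseudolik import (build_weight_matrix, combine, enumerate_pairs,
                        fit_all_pairs, rubin_pool, sandwich_empirical,
                        sandwich_literal_recipe, stack)

log = logging.getLogger("pairjm")

#: covariate-level joint tests reported by default (comorbidity tests its
#: three contrasts simultaneously)
WALD_COVARIATES = [
    ("age_2_11mo", ["age_2_11mo"]),
    ("patient_male", ["patient_male"]),
    ("comorbidity", ["comorbid_0", "comorbid_1", "comorbid_2"]),
    ("clinician_female", ["clinician_female"]),
    ("cadre_co", ["cadre_co"]),
    ("high_workload", ["high_workload"]),
    ("high_malaria", ["high_malaria"]),
    ("time_months", ["time_months"]),
    ("arm", ["arm"]),
    ("time_x_arm", ["time_x_arm"]),
]


@dataclass
class PipelineConfig:
    p: int = 3
    terms: list[str] | None = None          # default: all 13 design terms
    M: int = 3
    burn_in: int = 50
    between: int = 25
    n_quad: int = 9
    engine: str = "empirical"               # or "literal"
    seed: int = 0
    scale: str = "desk"                     # "desk" or "full"
    impute: bool = True
    input_csv: str | None = None
    generator: ds.GeneratorParams | None = None

    def __post_init__(self):
        if self.engine not in ("empirical", "literal"):
            raise ValueError(f"unknown sandwich engine {self.engine!r}")
        if self.scale == "desk":
            if self.p > 3 or self.M > 5:
                raise ValueError(
                    "desk scale caps p at 3 outcomes and M at 5 imputations"
                )
        elif self.scale != "full":
            raise ValueError(f"unknown scale preset {self.scale!r}")

    @property
    def k(self) -> int:
        return len(self.terms) if self.terms is not None else len(COEF_LABELS)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            base = ds.desk_params(p=cfg.p) if cfg.scale == "desk" \
                else ds.default_params(p=cfg.p)
            cfg.generator = dataclasses.replace(base, **gen)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.records = []

    def record(self, stage: str, **info):
        rec = {"stage": stage, "time": round(time.time(), 2), **info}
        self.records.append(rec)
        log.info("%s: %s", stage, {k: v for k, v in info.items()
                                   if k != "time"})
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")

    def artifact(self, stage: str, path: Path):
        self.record(stage, artifact=path.name, sha256=_sha256(path))


def _complete_cases(data: ds.TrialDataset) -> ds.TrialDataset:
    df = data.df
    mask = df[ds.MISSABLE].notna().all(axis=1)
    return ds.TrialDataset(df.loc[mask].reset_index(drop=True), data.p)


def _fit_and_combine(data, cfg: PipelineConfig, A, theta0s=None):
    fits = fit_all_pairs(data, cfg.p, terms=cfg.terms, n_quad=cfg.n_quad,
                         theta0s=theta0s)
    fit_list = list(fits.values())
    st = stack(fit_list, enumerate_pairs(cfg.p))
    if cfg.engine == "literal":
        st = sandwich_literal_recipe(st)
    else:
        st = sandwich_empirical(st)
    ce = combine(A, st)
    dmat = assoc.assemble_D(fit_list, st.index)
    thetas = {pr: f.theta for pr, f in fits.items()}
    flags = sorted({fl for f in fit_list for fl in f.flags})
    return ce, dmat, thetas, flags


def _save_combined(path: Path, ce, dmat, flags):
    np.savez(path, beta_star=ce.beta_star, sigma_star=ce.sigma_star,
             D=dmat.D, p=ce.p, k=ce.k, flags=np.array(flags, dtype=object))


def _load_combined(path: Path):
    z = np.load(path, allow_pickle=True)
    ce = pl.CombinedEstimates(beta_star=z["beta_star"],
                              sigma_star=z["sigma_star"],
                              p=int(z["p"]), k=int(z["k"]))
    dmat = assoc.DMatrix(D=z["D"])
    return ce, dmat, list(z["flags"])


def coef_frame(beta, se, p, labels) -> pd.DataFrame:
    rows = []
    k = len(labels)
    for r in range(p):
        for c, lab in enumerate(labels):
            i = r * k + c
            est, s = float(beta[i]), float(se[i])
            rows.append({
                "outcome": f"y{r + 1}", "coefficient": lab,
                "estimate": est, "se": s,
                "or": float(np.exp(est)),
                "ci_low": float(np.exp(est - 1.96 * s)),
                "ci_high": float(np.exp(est + 1.96 * s)),
                "degenerate_ci": bool(s < 1e-10),
            })
    return pd.DataFrame(rows)


def _wald_table(beta_cc, V_cc, beta_mi, V_mi, p, labels) -> pd.DataFrame:
    rows = []
    k = len(labels)
    for name, labs in WALD_COVARIATES:
        labs = [l for l in labs if l in labels]
        if not labs:
            continue
        spec = pl.concat_wald(
            [pl.build_L(l, p, k, labels=labels) for l in labs], name)
        row = {"covariate": name, "df": spec.df}
        res = pl.wald_joint_test(spec, beta_cc, V_cc)
        row["stat_cc"], row["p_cc"] = res.statistic, res.p_value
        if beta_mi is not None:
            res = pl.wald_joint_test(spec, beta_mi, V_mi)
            row["stat_mi"], row["p_mi"] = res.statistic, res.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute every stage, returning the in-memory results and writing the
    artifact tree. Stage sub-seeds are spawned from the master seed so any
    stage can be reproduced in isolation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "imputations").mkdir(exist_ok=True)
    (out / "combined").mkdir(exist_ok=True)
    runlog = _RunLog(out / "run.log")
    ss = np.random.SeedSequence(cfg.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
             for name, s in zip(["generate", "impute"], ss.spawn(2))}
    runlog.record("config", seed=cfg.seed, sub_seeds=seeds, p=cfg.p,
                  k=cfg.k, M=cfg.M, engine=cfg.engine, scale=cfg.scale)

    # --- data
    data_path = out / "data.csv"
    if data_path.exists():
        data = ds.read_csv(data_path)
        runlog.record("data", reused=True)
    else:
        if cfg.input_csv:
            data = ds.read_csv(cfg.input_csv)
        else:
            gen = cfg.generator
            if gen is None:
                gen = (ds.desk_params(p=cfg.p) if cfg.scale == "desk"
                       else ds.default_params(p=cfg.p))
            data = ds.generate(gen, seed=seeds["generate"])
        ds.write_csv(data, data_path)
        runlog.artifact("data", data_path)

    # --- exclusion filter
    data, report = ds.exclude_missing_cluster(data)
    (out / "excluded.json").write_text(json.dumps(report))
    runlog.artifact("exclude", out / "excluded.json")

    # --- imputation
    targets_missing = any(data.df[t].isna().any() for t in ds.MISSABLE)
    imputed = []
    if cfg.impute and targets_missing:
        imp_paths = [out / "imputations" / f"data_imp_{m + 1:03d}.csv"
                     for m in range(cfg.M)]
        if all(p.exists() for p in imp_paths):
            imputed = [ds.read_csv(p) for p in imp_paths]
            runlog.record("impute", reused=True)
        else:
            ispec = ImputationSpec(M=cfg.M, burn_in=cfg.burn_in,
                                   between=cfg.between, seed=seeds["impute"])
            stack_ = run_imputation(data, ispec)
            imputed = stack_.datasets
            for p_, d_ in zip(imp_paths, imputed):
                ds.write_csv(d_, p_)
                runlog.artifact("impute", p_)
            stack_.trace.to_csv(out / "imputations" / "trace.csv", index=False)
            runlog.artifact("impute", out / "imputations" / "trace.csv")

    # --- fits and combination
    A = build_weight_matrix(cfg.p, cfg.k)
    cc_data = _complete_cases(data)
    labels = cfg.terms if cfg.terms is not None else list(COEF_LABELS)

    cc_path = out / "combined" / "cc.npz"
    if cc_path.exists():
        ce_cc, dm_cc, cc_flags = _load_combined(cc_path)
        thetas = None
        runlog.record("fit_cc", reused=True)
    else:
        ce_cc, dm_cc, thetas, cc_flags = _fit_and_combine(cc_data, cfg, A)
        _save_combined(cc_path, ce_cc, dm_cc, cc_flags)
        runlog.record("fit_cc", n=cc_data.n_patients,
                      clusters=cc_data.n_clinicians, flags=cc_flags)

    per_imp, d_imps = [], []
    for m, d_ in enumerate(imputed):
        path = out / "combined" / f"imp_{m + 1:03d}.npz"
        if path.exists():
            ce, dm, fl = _load_combined(path)
            runlog.record(f"fit_imp_{m + 1}", reused=True)
        else:
            ce, dm, thetas, fl = _fit_and_combine(d_, cfg, A, theta0s=thetas)
            _save_combined(path, ce, dm, fl)
            runlog.record(f"fit_imp_{m + 1}", flags=fl)
        ce.m = m + 1
        per_imp.append(ce)
        d_imps.append(dm)

    # --- pooling
    pooled = None
    if per_imp:
        pooled = rubin_pool(per_imp)
        pf = coef_frame(pooled.beta_bar, pooled.se, cfg.p, labels)
        pf.to_csv(out / "pooled.csv", index=False)
        runlog.artifact("pool", out / "pooled.csv")

    ccf = coef_frame(ce_cc.beta_star, ce_cc.se, cfg.p, labels)
    ccf.to_csv(out / "combined_cc.csv", index=False)
    runlog.artifact("combine", out / "combined_cc.csv")

    # --- Wald tests
    wald = _wald_table(
        ce_cc.beta_star, ce_cc.sigma_star,
        pooled.beta_bar if pooled else None,
        pooled.V if pooled else None,
        cfg.p, labels)
    wald.to_csv(out / "wald.csv", index=False)
    runlog.artifact("wald", out / "wald.csv")

    # --- association
    results = {"data": data, "cc": ce_cc, "pooled": pooled, "wald": wald,
               "D_cc": dm_cc, "imputed": imputed}
    assoc.corr_from_D(dm_cc).to_csv(out / "varcorr_cc.csv")
    runlog.artifact("associate", out / "varcorr_cc.csv")
    pca_rows = []
    try:
        pca_cc = assoc.pca_correlation(assoc.corr_matrix_from_D(dm_cc),
                                       convention="column_standardized")
        pca_rows.append(("cc", pca_cc))
        results["pca_cc"] = pca_cc
    except ValueError as e:
        runlog.record("associate", pca_cc_error=str(e))
    if d_imps:
        dm_mi = assoc.average_over_imputations(d_imps)
        results["D_mi"] = dm_mi
        assoc.corr_from_D(dm_mi).to_csv(out / "varcorr_mi.csv")
        runlog.artifact("associate", out / "varcorr_mi.csv")
        try:
            pca_mi = assoc.pca_correlation(assoc.corr_matrix_from_D(dm_mi),
                                           convention="column_standardized")
            pca_rows.append(("mi", pca_mi))
            results["pca_mi"] = pca_mi
        except ValueError as e:
            runlog.record("associate", pca_mi_error=str(e))
    if pca_rows:
        frames = []
        for tag, res in pca_rows:
            head, _ = assoc.pca_table(res)
            head.insert(0, "analysis", tag)
            frames.append(head)
        pd.concat(frames).to_csv(out / "pca.csv", index=False)
        runlog.artifact("associate", out / "pca.csv")

    runlog.record("done", artifacts=sorted(
        p.name for p in out.rglob("*") if p.is_file()))
    return results


def report(run_dir) -> dict:
    """Summary tables from a completed run directory: odds ratios with 95%
    intervals (complete-case and pooled MI side by side) and the joint Wald
    table. Raises listing any missing stage outputs."""
    out = Path(run_dir)
    needed = {"combined_cc.csv": "combine", "wald.csv": "wald"}
    missing = [stage for f, stage in needed.items() if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing stages: {missing}")
    cc = pd.read_csv(out / "combined_cc.csv")
    tables = {"or_cc": cc, "wald": pd.read_csv(out / "wald.csv")}
    if (out / "pooled.csv").exists():
        tables["or_mi"] = pd.read_csv(out / "pooled.csv")
        merged = cc.merge(tables["or_mi"], on=["outcome", "coefficient"],
                          suffixes=("_cc", "_mi"))
        tables["or_side_by_side"] = merged
    return tables
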