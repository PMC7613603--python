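"""Pairwise joint models: fit, combine, and pool at desk scale.

A direct nine-outcome joint fit needs 9-dimensional quadrature and is
exactly what the pairwise strategy avoids, and even the 36 bivariate fits
on ~2100 records are hours of CPU. This driver therefore runs the complete
pipeline -- simulate, impute, fit all bivariate models per completed
dataset, stack, average with the 1/(p-1) weight matrix, sandwich variance,
Rubin pooling -- on a three-outcome desk-scale cohort (~60 clinicians),
which exercises every step of the full-scale analysis at a tractable size.

Writes: results/run_desk/* (combined_cc.csv, pooled.csv, wald.csv, ...)
"""

from pathlib import Path

import pandas as pd

from pairjm.pipeline import PipelineConfig, run_pipeline

SEED = 20160303
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    cfg = PipelineConfig(p=3, M=5, burn_in=100, between=50, n_quad=9,
                         seed=SEED, scale="desk")
    res = run_pipeline(cfg, OUT / "run_desk")

    cc, pooled = res["cc"], res["pooled"]
    print(f"complete-case analysis: {res['data'].n_patients} admissions, "
          f"{len(cc.beta_star)} combined coefficients "
          f"(p=3 outcomes x k=13 terms)")
    if pooled is not None:
        gain = 100 * (1 - pooled.se.mean() / cc.se.mean())
        print(f"pooled over M={pooled.M} imputations; mean SE changed by "
              f"{-gain:+.1f}% relative to complete case")
    side = pd.read_csv(OUT / "run_desk" / "pooled.csv")
    print(side.head(6).to_string(index=False))


if __name__ == "__main__":
    main()
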