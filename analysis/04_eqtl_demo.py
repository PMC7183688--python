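#!/usr/bin/env python
"""eQTL demonstration: opposite-direction expression effects of one variant.

Simulates two genes measured on the same 600 genotyped samples across four
ethnicity-like groups: one with a negative per-allele effect (risk allele
lowering expression, the suppressor-gene pattern) and one with a positive
effect (risk allele raising expression, the enhancer-gene pattern), then
recovers both with the covariate-adjusted additive linear model.

Writes results/eqtl/eqtl_results.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from epikit.eqtl import ExpressionMatrix, eqtl_scan
from epikit.simulate import ExpressionConfig, simulate_expression

OUT = Path(__file__).resolve().parent.parent / "results" / "eqtl"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=17)
    args = parser.parse_args()

    cfg_down = ExpressionConfig(n_samples=600, effect=-0.5, gene_id="gene_down")
    mat_down, dosage, groups = simulate_expression(cfg_down, args.seed)
    cfg_up = ExpressionConfig(n_samples=600, effect=0.8, gene_id="gene_up")
    mat_up, _, _ = simulate_expression(cfg_up, args.seed + 1,
                                       dosage=dosage["snp1"].to_numpy())
    matrix = ExpressionMatrix(pd.concat([mat_down.frame, mat_up.frame]))
    results = eqtl_scan(matrix, dosage, [("gene_down", "snp1"), ("gene_up", "snp1")],
                        covariates=groups)
    frame = pd.DataFrame([{
        "gene_id": r.gene_id, "snp_id": r.snp_id, "beta": r.beta, "se": r.se,
        "t": r.t_statistic, "p": r.p_value, "n": r.n_samples,
        "direction": r.direction,
    } for r in results])
    OUT.mkdir(parents=True, exist_ok=True)
    frame.to_csv(OUT / "eqtl_results.tsv", sep="\t", index=False, float_format="%.6g")
    print(frame.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
    print(f"\nTrue per-allele effects were -0.5 and +0.8; results in {OUT}")


if __name__ == "__main__":
    main()
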