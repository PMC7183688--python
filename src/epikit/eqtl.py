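"""Additive linear-model eQTL fitting.

Expression of one gene is regressed on risk-allele dosage (0/1/2) by ordinary
least squares, with an optional unordered categorical covariate (e.g. ethnic
background) entered as one-hot indicator columns against the lexicographically
first level. The dosage coefficient is tested with a two-sided t-test on
n − p residual degrees of freedom. Expression values are used as provided —
any normalization or log transform is upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist


class MonomorphicError(ValueError):
    """Dosage is constant: no eQTL effect is estimable."""


@dataclass(frozen=True)
class EqtlResult:
    gene_id: str
    snp_id: str
    beta: float
    se: float
    t_statistic: float
    p_value: float
    n_samples: int

    @property
    def direction(self) -> str:
        """Expression change associated with each added risk allele."""
        return "increased" if self.beta > 0 else ("decreased" if self.beta < 0 else "flat")


class ExpressionMatrix:
    """Genes × samples expression values with aligned sample ids."""

    def __init__(self, frame: pd.DataFrame):
        if frame.columns.duplicated().any():
            raise ValueError("duplicated sample ids in expression matrix")
        values = frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        self.frame = frame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    def gene(self, gene_id: str) -> pd.Series:
        return self.frame.loc[gene_id]

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    return ExpressionMatrix(pd.read_csv(path, sep="\t", index_col=0))


def read_dosage_csv(path: str | Path) -> pd.DataFrame:
    """Dosage CSV: sample_id column then one 0/1/2 column per SNP."""
    return pd.read_csv(path, index_col="sample_id")


def fit_eqtl(expression: np.ndarray | pd.Series, dosage: np.ndarray,
             covariates: Sequence | None = None,
             gene_id: str = "", snp_id: str = "") -> EqtlResult:
    """OLS fit of expression on additive dosage with categorical adjustment.

    ``covariates`` is a length-n factor (any hashable labels); every level
    must have at least 2 samples. The reference level is the lexicographic
    first, so a single-level factor reduces exactly to simple regression.
    """
    y = np.asarray(expression, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if y.shape != d.shape:
        raise ValueError("expression and dosage lengths differ")
    if np.ptp(d) == 0:
        raise MonomorphicError(f"{snp_id or 'dosage'} is constant; eQTL undefined")
    cols = [np.ones_like(d), d]
    names = ["intercept", "dosage"]
    if covariates is not None:
        fac = pd.Series(list(covariates))
        if len(fac) != len(y):
            raise ValueError("covariate length differs from sample count")
        levels = sorted(fac.unique())
        counts = fac.value_counts()
        thin = [lv for lv in levels if counts[lv] < 2]
        if thin:
            raise ValueError(f"covariate level(s) with < 2 samples: {thin}")
        for lv in levels[1:]:
            cols.append((fac == lv).to_numpy(dtype=float))
            names.append(f"group[{lv}]")
    X = np.column_stack(cols)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than parameters ({p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    b = float(beta[1])
    tstat = b / se if se > 0 else np.inf * np.sign(b)
    pval = float(2.0 * t_dist.sf(abs(tstat), df)) if np.isfinite(tstat) else 0.0
    return EqtlResult(gene_id=gene_id, snp_id=snp_id, beta=b, se=se,
                      t_statistic=float(tstat), p_value=pval, n_samples=n)


def eqtl_scan(matrix: ExpressionMatrix, dosages: pd.DataFrame,
              pairs: Sequence[tuple[str, str]],
              covariates: pd.Series | None = None) -> list[EqtlResult]:
    """One :func:`fit_eqtl` per requested (gene, SNP) pair.

    No multiple-testing correction is applied: the intended use is a small
    set of pre-specified candidate pairs. Sample ids of the expression
    matrix, dosage table and covariate series must match exactly.
    """
    samples = matrix.sample_ids
    missing = [s for s in samples if s not in dosages.index]
    if missing:
        raise ValueError(f"sample ids missing from dosage table: {missing}")
    dosages = dosages.loc[samples]
    cov = None
    if covariates is not None:
        missing = [s for s in samples if s not in covariates.index]
        if missing:
            raise ValueError(f"sample ids missing from covariates: {missing}")
        cov = covariates.loc[samples].to_list()
    out = []
    for gene_id, snp_id in pairs:
        out.append(fit_eqtl(matrix.gene(gene_id).to_numpy(),
                            dosages[snp_id].to_numpy(),
                            covariates=cov, gene_id=gene_id, snp_id=snp_id))
    return out
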