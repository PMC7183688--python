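"""Knockdown-assay synergy arithmetic on qPCR Ct values.

Four cell-line conditions are compared, each defined by relatively high or
low levels of two proteins (an NF-κB suppressor, A20/TNFAIP3, and an NF-κB
enhancer, UBE2L3/UBCH7):

- ``high_a20_low_ube`` — no A20 knockdown, UBE knockdown: the *reference*;
- ``low_a20_low_ube``  — both knocked down: the *A20-reduction* effect;
- ``high_a20_high_ube`` — no knockdown: the *UBE-augment* effect;
- ``low_a20_high_ube`` — A20 knockdown only: the *combined* effect.

Relative mRNA levels use the comparative-Ct (ΔΔCt, Livak) method with
amplification efficiency fixed at 2: ΔCt = Ct_target − Ct_housekeeping per
measurement, ΔΔCt = mean ΔCt(condition) − mean ΔCt(reference), fold =
2^(−ΔΔCt). The synergy statistic is

    ŝ = combined effect ÷ (reduction effect × augment effect),

ŝ > 1 meaning the two perturbations compose super-multiplicatively.
Significance per contrast is a Welch two-sample t-test on the replicate ΔCt
values (the variance-stabilized scale), starred at p ≤ 0.05 / 0.01 / 0.001 /
0.0001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

REFERENCE = "high_a20_low_ube"
REDUCTION = "low_a20_low_ube"
AUGMENT = "high_a20_high_ube"
COMBINED = "low_a20_high_ube"
CONDITIONS = (REFERENCE, REDUCTION, AUGMENT, COMBINED)

#: long-format qPCR CSV columns
QPCR_COLUMNS = ("condition", "gene", "timepoint_h", "replicate", "ct_target", "ct_gapdh")

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class SignificanceAnnotation:
    p_value: float
    stars: str


@dataclass(frozen=True)
class SynergyEstimate:
    """Per-timepoint fold effects of the three contrasts and their synergy ŝ."""

    gene: str
    timepoint: float
    effect_reduction: float
    effect_augment: float
    effect_combined: float
    s_hat: float

    @property
    def label(self) -> str:
        if np.isclose(self.s_hat, 1.0):
            return "multiplicative"
        return "synergistic" if self.s_hat > 1.0 else "sub-multiplicative"


def annotate(p_value: float) -> SignificanceAnnotation:
    """Star annotation with ≤ thresholds; stars are monotone in p."""
    if not (0.0 <= p_value <= 1.0):
        raise ValueError(f"p-value out of [0,1]: {p_value}")
    for thr, stars in STAR_THRESHOLDS:
        if p_value <= thr:
            return SignificanceAnnotation(p_value, stars)
    return SignificanceAnnotation(p_value, "ns")


def read_qpcr_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in QPCR_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"qPCR CSV missing columns: {missing}")
    return validate_qpcr(frame)


def validate_qpcr(frame: pd.DataFrame) -> pd.DataFrame:
    for col in ("ct_target", "ct_gapdh"):
        vals = frame[col].to_numpy(dtype=float)
        if not ((vals > 0) & (vals < 45)).all():
            bad = int(np.argmax(~((vals > 0) & (vals < 45))))
            raise ValueError(f"row {bad}: {col}={vals[bad]} outside (0, 45)")
    unknown = set(frame["condition"]) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown conditions {sorted(unknown)}; expected {CONDITIONS}")
    return frame


def delta_ct(records: pd.DataFrame) -> np.ndarray:
    """Per-measurement ΔCt = Ct_target − Ct_housekeeping."""
    return records["ct_target"].to_numpy(dtype=float) - records["ct_gapdh"].to_numpy(dtype=float)


def ddct_fold(records: pd.DataFrame, reference_records: pd.DataFrame) -> float:
    """Comparative-Ct fold change of one condition cell versus its matched
    reference cell: 2^−(mean ΔCt_cond − mean ΔCt_ref)."""
    if len(reference_records) == 0:
        raise ValueError("reference records missing for ΔΔCt")
    if len(records) == 0:
        raise ValueError("condition records missing for ΔΔCt")
    ddct = float(np.mean(delta_ct(records)) - np.mean(delta_ct(reference_records)))
    return float(2.0 ** (-ddct))


def synergy_s(effect_reduction: float, effect_augment: float,
              effect_combined: float, gene: str = "", timepoint: float = np.nan,
              ) -> SynergyEstimate:
    """ŝ = combined ÷ (reduction × augment); all folds must be positive."""
    if min(effect_reduction, effect_augment, effect_combined) <= 0:
        raise ValueError("fold changes must be positive")
    return SynergyEstimate(
        gene=gene, timepoint=timepoint,
        effect_reduction=float(effect_reduction),
        effect_augment=float(effect_augment),
        effect_combined=float(effect_combined),
        s_hat=float(effect_combined / (effect_reduction * effect_augment)),
    )


def condition_contrast(dataset: pd.DataFrame, gene: str, timepoint: float,
                       ) -> tuple[SynergyEstimate, dict[str, SignificanceAnnotation]]:
    """Folds, ŝ, and Welch-t star annotations for one gene × timepoint cell.

    Each of the three non-reference conditions is contrasted against the
    reference on the ΔCt scale. Cells with fewer than 2 replicates in either
    arm get no test (warning), but folds are still reported.
    """
    cell = dataset[(dataset["gene"] == gene) & (dataset["timepoint_h"] == timepoint)]
    by_cond = {c: cell[cell["condition"] == c] for c in CONDITIONS}
    if len(by_cond[REFERENCE]) == 0:
        raise ValueError(f"{gene} @ {timepoint} h: reference condition missing")
    folds = {}
    annotations: dict[str, SignificanceAnnotation] = {}
    ref_dct = delta_ct(by_cond[REFERENCE])
    for cond in (REDUCTION, AUGMENT, COMBINED):
        folds[cond] = ddct_fold(by_cond[cond], by_cond[REFERENCE])
        dct = delta_ct(by_cond[cond])
        if len(dct) < 2 or len(ref_dct) < 2:
            warnings.warn(
                f"{gene} @ {timepoint} h, {cond}: < 2 replicates; t-test skipped",
                stacklevel=2,
            )
            continue
        if np.var(dct) == 0.0 and np.var(ref_dct) == 0.0:
            # degenerate zero-variance cell: no t statistic is defined
            warnings.warn(
                f"{gene} @ {timepoint} h, {cond}: zero variance; t-test skipped",
                stacklevel=2,
            )
            continue
        res = ttest_ind(dct, ref_dct, equal_var=False)
        annotations[cond] = annotate(float(res.pvalue))
    est = synergy_s(folds[REDUCTION], folds[AUGMENT], folds[COMBINED],
                    gene=gene, timepoint=timepoint)
    return est, annotations


def synergy_table(dataset: pd.DataFrame) -> pd.DataFrame:
    """All gene × timepoint contrasts as a tidy report frame."""
    rows = []
    for gene in sorted(dataset["gene"].unique()):
        for tp in sorted(dataset.loc[dataset["gene"] == gene, "timepoint_h"].unique()):
            est, ann = condition_contrast(dataset, gene, tp)
            row = {
                "gene": gene, "timepoint_h": tp,
                "fold_reduction": est.effect_reduction,
                "fold_augment": est.effect_augment,
                "fold_combined": est.effect_combined,
                "s_hat": est.s_hat,
            }
            for cond in (REDUCTION, AUGMENT, COMBINED):
                a = ann.get(cond)
                row[f"p_{cond}"] = a.p_value if a else np.nan
                row[f"stars_{cond}"] = a.stars if a else ""
            rows.append(row)
    return pd.DataFrame(rows)
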