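"""Gene-gene interaction (epistasis) statistics for case-control data.

Two scales are implemented:

*Multiplicative* — the joint-exposure odds ratio divided by the product of the
single-exposure odds ratios, OR_int = OR_12 / (OR_1 · OR_2). In a logistic
model with a product term this equals exp(β3). OR_int > 1 is synergistic
(super-multiplicative), < 1 antagonistic.

*Additive (Rothman)* — relative excess risk due to interaction
RERI = RR_11 − RR_10 − RR_01 + 1, attributable proportion AP = RERI / RR_11,
and synergy index S = (RR_11 − 1) / ((RR_10 − 1) + (RR_01 − 1)). In
case-control data odds ratios stand in for relative risks under the
rare-disease assumption, as epidemiology packages conventionally do; the
estimates carry an ``rr_approximated_by_or`` flag. Delta-method 95% CIs for
AP are available when a covariance matrix of the log-RRs is supplied.

The stratified analysis follows the six-cell layout used for a rare × common
SNP pair: the rare SNP collapsed to risk-allele carriage (N = non-carrier,
R = carrier), the common SNP kept as three genotypes (nn/nr/rr), reference
stratum (N, nn).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .association import (
    Z_95,
    AssociationEstimate,
    LogisticFit,
    build_design,
    crude_or_2x2,
    fit_logistic,
)
from .genotype_io import CodingScheme, SnpSpec, SubjectTable

A_LEVELS = ("N", "R")
B_LEVELS = ("nn", "nr", "rr")
REFERENCE_KEY = ("N", "nn")

StratumKey = tuple[str, str]


class EmptyReferenceError(ValueError):
    """The reference stratum has no cases or no controls: no reference odds."""


@dataclass(frozen=True)
class StratumCell:
    controls: int
    cases: int


class StratifiedEpistasisTable:
    """Six-cell (carriage × genotype) case/control table with a reference stratum."""

    def __init__(self, cells: Mapping[StratumKey, StratumCell],
                 reference: StratumKey = REFERENCE_KEY):
        for key, cell in cells.items():
            if cell.controls < 0 or cell.cases < 0:
                raise ValueError(f"stratum {key}: negative count")
        if reference not in cells:
            raise ValueError(f"reference stratum {reference} missing")
        self.cells = dict(cells)
        self.reference = reference
        ref = self.cells[reference]
        if ref.controls == 0 or ref.cases == 0:
            raise EmptyReferenceError(
                f"reference stratum {reference} has controls={ref.controls}, "
                f"cases={ref.cases}; reference odds undefined"
            )

    @property
    def keys(self) -> list[StratumKey]:
        return [(a, b) for a in A_LEVELS for b in B_LEVELS if (a, b) in self.cells]

    def total_controls(self) -> int:
        return sum(c.controls for c in self.cells.values())

    def total_cases(self) -> int:
        return sum(c.cases for c in self.cells.values())

    def crude_or(self, key: StratumKey) -> AssociationEstimate:
        """Crude OR of one stratum versus the reference stratum."""
        cell, ref = self.cells[key], self.cells[self.reference]
        return crude_or_2x2(cell.cases, ref.cases, cell.controls, ref.controls)

    def crude_ors(self) -> dict[StratumKey, AssociationEstimate]:
        return {k: self.crude_or(k) for k in self.keys if k != self.reference}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in self.keys:
            cell = self.cells[key]
            rows.append({"snpA_level": key[0], "snpB_level": key[1],
                         "controls": cell.controls, "cases": cell.cases})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class InteractionEstimate:
    """Multiplicative interaction: OR_int = OR_12 / (OR_1 · OR_2)."""

    or_1: float
    or_2: float
    or_12: float
    or_int: float
    source: str  # "stratified" | "regression"
    p_value: float | None = None

    def __post_init__(self) -> None:
        if min(self.or_1, self.or_2, self.or_12) <= 0:
            raise ValueError("component ORs must be positive")

    @property
    def label(self) -> str:
        if np.isclose(self.or_int, 1.0):
            return "none"
        return "synergistic" if self.or_int > 1.0 else "antagonistic"


@dataclass(frozen=True)
class AdditiveInteractionEstimate:
    """Rothman additive-scale interaction measures."""

    rr_10: float
    rr_01: float
    rr_11: float
    reri: float
    ap: float
    s_index: float | None          # None when both single RRs are 1 (undefined)
    ap_ci_low: float | None = None
    ap_ci_high: float | None = None
    rr_approximated_by_or: bool = True


def stratify(table: SubjectTable, snp_a: SnpSpec, snp_b: SnpSpec) -> StratifiedEpistasisTable:
    """Cross-tabulate carriage of SNP-A's risk allele against SNP-B genotype."""
    sub = table.complete_cases([snp_a.snp_id, snp_b.snp_id])
    dos_a = sub.dosage(snp_a.snp_id, CodingScheme.DOMINANT)
    dos_b = sub.dosage(snp_b.snp_id, CodingScheme.ADDITIVE)
    status = sub.status
    cells = {}
    for ia, a in enumerate(A_LEVELS):
        for ib, b in enumerate(B_LEVELS):
            mask = (dos_a == ia) & (dos_b == ib)
            cells[(a, b)] = StratumCell(
                controls=int((mask & (status == 0)).sum()),
                cases=int((mask & (status == 1)).sum()),
            )
    return StratifiedEpistasisTable(cells)


def or_int_from_ors(or_12: float, or_1: float, or_2: float,
                    source: str = "stratified") -> InteractionEstimate:
    """Worked-example mode: OR_int from pre-computed (possibly adjusted) ORs."""
    if min(or_12, or_1, or_2) <= 0:
        raise ValueError("ORs must be positive")
    return InteractionEstimate(
        or_1=float(or_1), or_2=float(or_2), or_12=float(or_12),
        or_int=float(or_12 / (or_1 * or_2)), source=source,
    )


def stratified_or_int(strata: StratifiedEpistasisTable,
                      doubly: StratumKey = ("R", "rr"),
                      single_a: StratumKey = ("R", "nn"),
                      single_b: StratumKey = ("N", "rr")) -> InteractionEstimate:
    """OR_int from crude stratum odds ratios versus the reference stratum."""
    ors = {}
    for name, key in (("doubly", doubly), ("single_a", single_a), ("single_b", single_b)):
        try:
            ors[name] = strata.crude_or(key).odds_ratio
        except ValueError as e:
            raise ValueError(f"stratum {key} OR undefined: {e}") from None
    return or_int_from_ors(ors["doubly"], ors["single_a"], ors["single_b"])


def adjusted_stratum_ors(table: SubjectTable, snp_a: SnpSpec, snp_b: SnpSpec,
                         covariates: tuple[str, ...] = ("age", "sex"),
                         ) -> tuple[dict[StratumKey, AssociationEstimate], LogisticFit]:
    """Covariate-adjusted per-stratum ORs from one genotype-categorical logistic
    fit (an indicator per non-reference stratum), mirroring adjusted stratified
    tables in case-control reports."""
    sub = table.complete_cases([snp_a.snp_id, snp_b.snp_id])
    dos_a = sub.dosage(snp_a.snp_id, CodingScheme.DOMINANT)
    dos_b = sub.dosage(snp_b.snp_id, CodingScheme.ADDITIVE)
    terms: dict[str, np.ndarray] = {}
    keys = []
    for ia, a in enumerate(A_LEVELS):
        for ib, b in enumerate(B_LEVELS):
            if (a, b) == REFERENCE_KEY:
                continue
            keys.append((a, b))
            terms[f"{a}/{b}"] = ((dos_a == ia) & (dos_b == ib)).astype(float)
    design, y = build_design(sub, terms, covariates)
    fit = fit_logistic(design, y)
    return {key: fit.wald(f"{key[0]}/{key[1]}") for key in keys}, fit


def regression_or_int(table: SubjectTable, snp_a: SnpSpec, snp_b: SnpSpec,
                      coding_a: CodingScheme | str = CodingScheme.DOMINANT,
                      coding_b: CodingScheme | str = CodingScheme.ADDITIVE,
                      covariates: tuple[str, ...] = (),
                      ) -> tuple[InteractionEstimate, LogisticFit]:
    """Product-term logistic interaction test.

    Model: logit P(case) = β0 + β1·A + β2·B + β3·A·B (+ covariates), with
    A, B the coded dosages. Returns exp(β3) as OR_int with its Wald p, plus
    the full fit. Default coding is carriage for SNP-A (the rare variant) and
    additive dosage for SNP-B, matching the stratified layout.
    """
    sub = table.complete_cases([snp_a.snp_id, snp_b.snp_id])
    a = sub.dosage(snp_a.snp_id, CodingScheme(coding_a))
    b = sub.dosage(snp_b.snp_id, CodingScheme(coding_b))
    design, y = build_design(
        sub, {"snp_a": a, "snp_b": b, "snp_a_x_snp_b": a * b}, covariates
    )
    fit = fit_logistic(design, y)
    if not fit.converged:
        raise RuntimeError(f"interaction fit did not converge: {fit.message}")
    w = fit.wald("snp_a_x_snp_b")
    beta = fit.coefficients
    or_1 = float(np.exp(beta["snp_a"]))
    or_2 = float(np.exp(beta["snp_b"]))
    or_12 = float(np.exp(beta["snp_a"] + beta["snp_b"] + beta["snp_a_x_snp_b"]))
    est = InteractionEstimate(or_1=or_1, or_2=or_2, or_12=or_12,
                              or_int=w.odds_ratio, source="regression",
                              p_value=w.p_value)
    return est, fit


def rothman_additive(rr_10: float, rr_01: float, rr_11: float,
                     covariance: np.ndarray | None = None,
                     rr_approximated_by_or: bool = True) -> AdditiveInteractionEstimate:
    """RERI, AP and synergy index S from the three joint/single relative risks.

    ``covariance`` is the 3×3 covariance of (log rr_10, log rr_01, log rr_11);
    when given, a delta-method 95% CI for AP is computed. S is undefined
    (returned as None) when (rr_10 − 1) + (rr_01 − 1) = 0.
    """
    if min(rr_10, rr_01, rr_11) <= 0:
        raise ValueError("relative risks must be positive")
    reri = rr_11 - rr_10 - rr_01 + 1.0
    ap = reri / rr_11
    denom = (rr_10 - 1.0) + (rr_01 - 1.0)
    s_index = None if np.isclose(denom, 0.0) else float((rr_11 - 1.0) / denom)
    ci_low = ci_high = None
    if covariance is not None:
        cov = np.asarray(covariance, dtype=float)
        if cov.shape != (3, 3):
            raise ValueError("covariance must be 3x3 for (log rr_10, log rr_01, log rr_11)")
        # gradient of AP wrt the log-RRs
        grad = np.array([
            -rr_10 / rr_11,
            -rr_01 / rr_11,
            (rr_10 + rr_01 - 1.0) / rr_11,
        ])
        var = float(grad @ cov @ grad)
        half = Z_95 * np.sqrt(max(var, 0.0))
        ci_low, ci_high = float(ap - half), float(ap + half)
    return AdditiveInteractionEstimate(
        rr_10=float(rr_10), rr_01=float(rr_01), rr_11=float(rr_11),
        reri=float(reri), ap=float(ap), s_index=s_index,
        ap_ci_low=ci_low, ap_ci_high=ci_high,
        rr_approximated_by_or=rr_approximated_by_or,
    )


def additive_from_logistic(fit: LogisticFit, term_a: str, term_b: str,
                           term_ab: str) -> AdditiveInteractionEstimate:
    """Additive-interaction measures from a product-term logistic fit.

    Uses OR_10 = e^{βa}, OR_01 = e^{βb}, OR_11 = e^{βa+βb+βab} as RR
    approximations; the log-RR covariance is the linear transform of the
    coefficient covariance, so the AP delta-method CI accounts for the
    correlation among the three estimates.
    """
    idx = list(fit.coefficients.index)
    A = np.zeros((3, len(idx)))
    A[0, idx.index(term_a)] = 1.0
    A[1, idx.index(term_b)] = 1.0
    for j, t in enumerate((term_a, term_b, term_ab)):
        A[2, idx.index(t)] = 1.0
    b = A @ fit.coefficients.to_numpy()
    cov = A @ fit.covariance.to_numpy() @ A.T
    return rothman_additive(float(np.exp(b[0])), float(np.exp(b[1])),
                            float(np.exp(b[2])), covariance=cov)
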