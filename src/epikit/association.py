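"""Single-SNP association statistics for case-control cohorts.

Crude odds ratios come straight from 2×2 counts with Woolf standard errors;
adjusted estimates come from a maximum-likelihood logistic regression fitted
by iteratively reweighted least squares (IRLS) implemented here. Confidence
intervals are Wald intervals on the log-odds scale, exponentiated — the
convention behind symmetric printed intervals like "1.9 (1.6–2.4)".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .genotype_io import CodingScheme, SnpSpec, SubjectTable

Z_95 = 1.959963984540054  # norm.ppf(0.975)


class DegenerateTableError(ValueError):
    """A contingency table with an all-zero margin has no defined odds ratio."""


@dataclass(frozen=True)
class AssociationEstimate:
    """Odds ratio with Wald 95% CI and p-value."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float
    se: float
    continuity_corrected: bool = False

    def report(self) -> str:
        """Table-style rendering, OR and CI to one decimal."""
        return f"{self.odds_ratio:.1f} ({self.ci_low:.1f}–{self.ci_high:.1f})"


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit.

    ``coefficients`` and ``covariance`` are indexed by design column names
    (``intercept`` first). ``converged`` is False under suspected separation
    (diverging coefficients) — estimates are then untrustworthy and flagged,
    not silently returned.
    """

    coefficients: pd.Series
    covariance: pd.DataFrame
    log_likelihood: float
    n_iterations: int
    converged: bool
    message: str = ""

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance)), index=self.coefficients.index)

    def wald(self, term: str) -> AssociationEstimate:
        """Wald OR, 95% CI and two-sided p for one coefficient."""
        b = float(self.coefficients[term])
        s = float(self.se[term])
        z = b / s if s > 0 else np.inf * np.sign(b)
        return AssociationEstimate(
            odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - Z_95 * s)),
            ci_high=float(np.exp(b + Z_95 * s)),
            p_value=float(2.0 * norm.sf(abs(z))),
            beta=b,
            se=s,
        )


@dataclass(frozen=True)
class MultipleTestingResult:
    n_tests: int
    alpha_family: float
    alpha_per_test: float
    decisions: tuple[bool, ...]


def crude_or_2x2(exposed_cases: float, unexposed_cases: float,
                 exposed_controls: float, unexposed_controls: float) -> AssociationEstimate:
    """Crude odds ratio from a 2×2 table with Woolf SE.

    OR = (exposed_cases · unexposed_controls) / (unexposed_cases · exposed_controls).
    Any zero cell triggers the Haldane–Anscombe +0.5 correction to all four
    cells, flagged via ``continuity_corrected``; an all-zero margin is
    degenerate and raises.
    """
    a, b, c, d = exposed_cases, unexposed_cases, exposed_controls, unexposed_controls
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DegenerateTableError("2x2 table has an all-zero margin; OR undefined")
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    beta = float(np.log((a * d) / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = beta / se
    return AssociationEstimate(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)),
        p_value=float(2.0 * norm.sf(abs(z))),
        beta=beta,
        se=se,
        continuity_corrected=corrected,
    )


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = Σ y·η − log(1 + e^η), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(design: pd.DataFrame | np.ndarray, outcome: np.ndarray,
                 max_iter: int = 50, tol_score: float = 1e-8,
                 tol_loglik: float = 1e-13) -> LogisticFit:
    """Fit a logistic regression by Newton/IRLS with step-halving.

    ``design`` must already contain the intercept column. Convergence is
    declared when the largest score (gradient) component falls below
    ``tol_score`` or the relative log-likelihood change below ``tol_loglik``.
    Diverging coefficients (|β| > 15 on standardized-scale data is far beyond
    any plausible odds ratio) are flagged as suspected separation. The
    likelihood-stall tolerance sits at the double-precision noise floor so the
    score criterion governs ordinary fits; Newton's quadratic convergence then
    delivers coefficients accurate to ~1e-10.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")

    beta = np.zeros(p)
    eta = X @ beta
    ll = _log_likelihood(eta, y)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol_score:
            converged = True
            break
        info = X.T @ (X * w[:, None])
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            message = "singular information matrix (collinear design?)"
            break
        # step-halving: never accept a likelihood decrease
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new = _log_likelihood(X @ cand, y)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step * delta
        eta = X @ beta
        if abs(ll_new - ll) < tol_loglik * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    if np.max(np.abs(beta)) > 15.0:
        converged = False
        message = "suspected complete or quasi-complete separation (diverging coefficients)"
    return LogisticFit(
        coefficients=pd.Series(beta, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        log_likelihood=_log_likelihood(X @ beta, y),
        n_iterations=it,
        converged=converged,
        message=message,
    )


def build_design(table: SubjectTable, terms: dict[str, np.ndarray],
                 covariates: tuple[str, ...] = ()) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble intercept + named term columns + covariate columns, dropping
    subjects with any missing value (complete-case)."""
    cols = {"intercept": np.ones(len(table))}
    cols.update({k: np.asarray(v, dtype=float) for k, v in terms.items()})
    for cov in covariates:
        if cov not in table.frame.columns:
            raise ValueError(f"covariate {cov!r} not in subject table")
        cols[cov] = table.frame[cov].to_numpy(dtype=float)
    design = pd.DataFrame(cols)
    y = table.status.astype(float)
    keep = design.notna().all(axis=1).to_numpy()
    return design[keep].reset_index(drop=True), y[keep]


def snp_association(table: SubjectTable, snp: SnpSpec,
                    scheme: CodingScheme | str = CodingScheme.ADDITIVE,
                    covariates: tuple[str, ...] = ()) -> AssociationEstimate:
    """Covariate-adjusted single-SNP association (Wald test on the dosage term).

    Default coding is additive risk-allele dosage, the usual trend test
    behind genome-wide logistic scans; dominant/recessive/genotype available.
    """
    scheme = CodingScheme(scheme)
    if scheme is CodingScheme.GENOTYPE:
        raise ValueError("snp_association reports a single OR; use additive/dominant/recessive")
    dosage = table.dosage(snp.snp_id, scheme)
    design, y = build_design(table, {snp.snp_id: dosage}, covariates)
    fit = fit_logistic(design, y)
    est = fit.wald(snp.snp_id)
    if not fit.converged:
        raise RuntimeError(f"logistic fit did not converge: {fit.message}")
    return est


def bonferroni(p_values, alpha_family: float = 0.05) -> MultipleTestingResult:
    """Family-wise Bonferroni correction: per-test threshold alpha/m."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("bonferroni requires at least one p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    thr = alpha_family / p.size
    return MultipleTestingResult(
        n_tests=int(p.size),
        alpha_family=float(alpha_family),
        alpha_per_test=float(thr),
        decisions=tuple(bool(x) for x in p < thr),
    )
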