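"""Multiplicative and additive (Rothman) interaction statistics."""

import numpy as np
import pandas as pd
import pytest

from epikit import datasets
from epikit.genotype_io import CodingScheme
from epikit.interaction import (
    EmptyReferenceError,
    StratifiedEpistasisTable,
    StratumCell,
    additive_from_logistic,
    or_int_from_ors,
    regression_or_int,
    rothman_additive,
    stratified_or_int,
    stratify,
)
from epikit.association import fit_logistic
from epikit.simulate import CohortConfig, simulate_cohort
from conftest import random_2x2x2_table


class TestStratify:
    def test_published_stratified_counts(self):
        table2 = datasets.load_table2()
        controls = [table2.cells[k].controls for k in table2.keys]
        cases = [table2.cells[k].cases for k in table2.keys]
        assert controls == [509, 999, 481, 63, 117, 38]
        assert cases == [232, 540, 297, 42, 129, 78]

    def test_tallies_match_generator_bookkeeping(self):
        cfg = CohortConfig(n_subjects=800, maf_a=0.2, maf_b=0.4)
        table, truth = simulate_cohort(cfg, seed=77)
        strat = stratify(table, cfg.snp_a, cfg.snp_b)
        dos_a, status = truth["dosage_a"], table.status
        dos_b = table.dosage("snpB", CodingScheme.ADDITIVE)
        expected = int(((dos_a == 1) & (dos_b == 2) & (status == 1)).sum())
        assert strat.cells[("R", "rr")].cases == expected
        assert strat.total_controls() + strat.total_cases() == 800

    def test_empty_reference_raises(self):
        cells = {("N", "nn"): StratumCell(controls=0, cases=5),
                 ("R", "rr"): StratumCell(controls=3, cases=4)}
        with pytest.raises(EmptyReferenceError):
            StratifiedEpistasisTable(cells)

    def test_all_control_input_has_no_reference_odds(self):
        frame = pd.DataFrame({
            "sample_id": ["a", "b"], "status": [0, 0],
            "snpA": ["TT", "TG"], "snpB": ["TT", "TG"],
        })
        from epikit.genotype_io import SnpSpec, SubjectTable
        table = SubjectTable(frame, [SnpSpec("snpA", "T", "G", "G"),
                                     SnpSpec("snpB", "T", "G", "T")])
        with pytest.raises(EmptyReferenceError):
            stratify(table, table.snps["snpA"], table.snps["snpB"])


class TestOrInt:
    def test_worked_examples_from_published_stratum_ors(self):
        high = or_int_from_ors(4.1, 1.3, 1.3)
        mid = or_int_from_ors(2.3, 1.3, 1.2)
        assert high.or_int == pytest.approx(4.1 / 1.69)
        assert round(high.or_int, 1) == 2.4
        assert round(mid.or_int, 1) == 1.5
        assert high.label == "synergistic"

    def test_crude_mode_on_published_counts(self):
        table2 = datasets.load_table2()
        est = stratified_or_int(table2)
        assert est.or_12 == pytest.approx(4.503, abs=2e-3)
        assert est.or_1 == pytest.approx(1.463, abs=2e-3)
        assert est.or_2 == pytest.approx(1.355, abs=2e-3)
        # below the published 2.4 because the printed ORs are age/sex-adjusted
        assert est.or_int == pytest.approx(2.273, abs=2e-3)

    def test_or_int_identity_holds(self):
        est = or_int_from_ors(3.7, 1.4, 1.1)
        assert est.or_int == pytest.approx(est.or_12 / (est.or_1 * est.or_2), abs=1e-9)

    def test_multiplicative_null_gives_unit_or_int(self):
        est = or_int_from_ors(1.3 * 1.7, 1.3, 1.7)
        assert est.or_int == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_exposure_label_swap(self):
        table2 = datasets.load_table2()
        fwd = stratified_or_int(table2, ("R", "rr"), ("R", "nn"), ("N", "rr"))
        swp = stratified_or_int(table2, ("R", "rr"), ("N", "rr"), ("R", "nn"))
        assert fwd.or_int == pytest.approx(swp.or_int, rel=1e-12)


def saturated_tables():
    rng = np.random.default_rng(314159)
    return [random_2x2x2_table(rng) for _ in range(50)]


class TestRegressionOrInt:
    @pytest.mark.parametrize("counts", saturated_tables()[:10],
                             ids=lambda c: f"tbl{abs(hash(c.tobytes())) % 10**6}")
    def test_saturated_fit_equals_stratified_cross_ratio(self, counts):
        """Principal oracle: on a 2×2×2 table the product-term coefficient
        equals the four-cell cross-ratio exactly."""
        rows_x, rows_y = [], []
        for a in (0, 1):
            for b in (0, 1):
                for status in (0, 1):
                    n = counts[a, b, status]
                    rows_x.extend([(1.0, a, b, a * b)] * n)
                    rows_y.extend([status] * n)
        X = pd.DataFrame(rows_x, columns=["intercept", "a", "b", "ab"])
        fit = fit_logistic(X, np.array(rows_y, dtype=float))
        # cross-ratio: OR_int = (OR_11 / (OR_10 * OR_01)) from the cell odds
        odds = counts[..., 1] / counts[..., 0]
        or_int = (odds[1, 1] / odds[0, 0]) / ((odds[1, 0] / odds[0, 0]) * (odds[0, 1] / odds[0, 0]))
        assert np.exp(fit.coefficients["ab"]) == pytest.approx(or_int, abs=1e-8)

    def test_or_int_identity_in_regression_mode(self):
        table, _ = simulate_cohort(CohortConfig(n_subjects=2500), seed=5)
        cfg = CohortConfig()
        est, fit = regression_or_int(table, cfg.snp_a, cfg.snp_b, covariates=("age", "sex"))
        assert est.source == "regression"
        assert est.or_int == pytest.approx(est.or_12 / (est.or_1 * est.or_2), rel=1e-9)
        assert est.or_int == pytest.approx(np.exp(fit.coefficients["snp_a_x_snp_b"]))


class TestRothmanAdditive:
    def test_published_stratum_ors_panel(self):
        # from the printed adjusted ORs; the published AP = 0.42 came from a
        # full adjusted individual-level analysis and is not expected to match
        est = rothman_additive(1.3, 1.3, 4.1)
        assert est.reri == pytest.approx(2.5)
        assert est.ap == pytest.approx(2.5 / 4.1, abs=1e-9)
        assert est.s_index == pytest.approx(3.1 / 0.6)

    def test_exact_additivity_is_null(self):
        est = rothman_additive(1.5, 2.0, 2.5)
        assert est.reri == pytest.approx(0.0, abs=1e-12)
        assert est.ap == pytest.approx(0.0, abs=1e-12)

    def test_global_null_s_undefined(self):
        est = rothman_additive(1.0, 1.0, 1.0)
        assert est.reri == 0.0 and est.ap == 0.0
        assert est.s_index is None

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            rothman_additive(0.0, 1.0, 2.0)

    def test_delta_method_se_matches_monte_carlo_propagation(self):
        """Oracle: propagate MVN noise on the log-RRs by simulation."""
        logs = np.log([1.4, 1.6, 3.2])
        cov = np.array([[0.010, 0.002, 0.004],
                        [0.002, 0.012, 0.005],
                        [0.004, 0.005, 0.020]])
        est = rothman_additive(*np.exp(logs), covariance=cov)
        rng = np.random.default_rng(8)
        draws = rng.multivariate_normal(logs, cov, size=200_000)
        rr = np.exp(draws)
        ap = (rr[:, 2] - rr[:, 0] - rr[:, 1] + 1) / rr[:, 2]
        mc_se = ap.std()
        delta_se = (est.ap_ci_high - est.ap_ci_low) / (2 * 1.959964)
        assert delta_se == pytest.approx(mc_se, rel=0.05)

    def test_additive_from_logistic_transform(self):
        cfg = CohortConfig(n_subjects=3000, maf_a=0.3, maf_b=0.3,
                           coding_a=CodingScheme.DOMINANT, coding_b=CodingScheme.DOMINANT,
                           beta_age=0.0, beta_sex=0.0)
        table, _ = simulate_cohort(cfg, seed=21)
        _, fit = regression_or_int(table, cfg.snp_a, cfg.snp_b,
                                   CodingScheme.DOMINANT, CodingScheme.DOMINANT)
        add = additive_from_logistic(fit, "snp_a", "snp_b", "snp_a_x_snp_b")
        b = fit.coefficients
        assert add.rr_10 == pytest.approx(np.exp(b["snp_a"]))
        assert add.rr_11 == pytest.approx(
            np.exp(b["snp_a"] + b["snp_b"] + b["snp_a_x_snp_b"]))
        assert add.ap_ci_low < add.ap < add.ap_ci_high
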