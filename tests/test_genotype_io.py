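"""Genotype data model, coding, counting, HWE and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2 as chi2_dist

from epikit import datasets
from epikit.genotype_io import (
    CodingScheme,
    GenotypeCounts,
    GenotypeParseError,
    SnpSpec,
    SubjectTable,
    hwe_test,
    normalize_genotype,
    read_ped,
    read_subject_table,
    tabulate_counts,
)
from epikit.simulate import CohortConfig, simulate_cohort


class TestSnpSpec:
    def test_risk_and_minor_are_independent(self):
        spec = SnpSpec("rs131654", "T", "G", allele_risk="T")
        assert spec.allele_risk == spec.allele_major  # risk can be the major allele
        assert spec.allele_nonrisk == "G"
        assert not spec.risk_is_minor

    @pytest.mark.parametrize("kwargs", [
        dict(allele_major="T", allele_minor="T", allele_risk="T"),
        dict(allele_major="T", allele_minor="G", allele_risk="A"),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SnpSpec("bad", **kwargs)


class TestCoding:
    @pytest.mark.parametrize("genotype,scheme,expected", [
        ("TT", "additive", 0), ("TG", "additive", 1), ("GG", "additive", 2),
        ("TT", "dominant", 0), ("TG", "dominant", 1), ("GG", "dominant", 1),
        ("TT", "recessive", 0), ("TG", "recessive", 0), ("GG", "recessive", 1),
    ])
    def test_risk_minor_dosages(self, snp_rare, snp_common, genotype, scheme, expected):
        frame = pd.DataFrame({"sample_id": ["x"], "status": [0],
                              "snpA": [genotype], "snpB": ["TT"]})
        table = SubjectTable(frame, [snp_rare, snp_common])
        assert table.dosage("snpA", scheme)[0] == expected

    def test_risk_major_orientation(self, toy_table):
        # snpB risk allele is the MAJOR T: TT is the risk homozygote
        np.testing.assert_array_equal(
            toy_table.dosage("snpB", CodingScheme.ADDITIVE), [2, 1, 0, 0, 1, 2])

    def test_genotype_scheme_two_indicators(self, toy_table):
        ind = toy_table.dosage("snpA", CodingScheme.GENOTYPE)
        np.testing.assert_array_equal(ind[:, 0], [0, 1, 0, 0, 1, 0])  # nr
        np.testing.assert_array_equal(ind[:, 1], [0, 0, 1, 0, 0, 1])  # rr

    @given(st.sampled_from(["TT", "TG", "GT", "GG"]))
    @settings(derandomize=True)
    def test_normalization_is_order_free(self, genotype):
        spec = SnpSpec("s", "T", "G", "G")
        assert normalize_genotype(genotype, spec) == normalize_genotype(genotype[::-1], spec)


class TestSubjectIo:
    def test_round_trip(self, tmp_path, snp_rare, snp_common):
        table, _ = simulate_cohort(CohortConfig(n_subjects=100), seed=5)
        path = tmp_path / "cohort.csv"
        table.write_csv(path)
        back = read_subject_table(path, [table.snps["snpA"], table.snps["snpB"]])
        pd.testing.assert_frame_equal(table.frame, back.frame, check_dtype=False)

    def test_bad_allele_names_row(self, tmp_path, snp_rare, snp_common):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,status,snpA,snpB\nA,0,TT,TT\nB,1,TA,TT\n")
        with pytest.raises(GenotypeParseError, match="row 1"):
            read_subject_table(path, [snp_rare, snp_common])

    def test_non_integer_status_rejected(self, tmp_path, snp_rare, snp_common):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,status,snpA,snpB\nA,control,TT,TT\n")
        with pytest.raises(GenotypeParseError, match="status"):
            read_subject_table(path, [snp_rare, snp_common])

    def test_ped_map_reader(self, tmp_path):
        (tmp_path / "toy.map").write_text("6 rsX 0 1000\n")
        (tmp_path / "toy.ped").write_text(
            "F1 I1 0 0 2 2 T G\nF2 I2 0 0 1 1 T T\nF3 I3 0 0 2 1 G G\n")
        table = read_ped(tmp_path / "toy.map", tmp_path / "toy.ped",
                         risk_alleles={"rsX": "G"})
        assert list(table.status) == [1, 0, 0]
        assert list(table.frame["sex"]) == [1, 0, 1]  # female = 1
        np.testing.assert_array_equal(table.dosage("rsX", "additive"), [1, 0, 2])


class TestTabulate:
    def test_published_counts_rare_snp(self):
        cc = datasets.load_table1()["rs2230926"]
        assert cc.controls.as_tuple() == (1989, 213, 5)
        assert cc.cases.as_tuple() == (1069, 240, 9)

    def test_published_counts_risk_major_snp(self):
        # risk = major T, so nn is the GG cell
        cc = datasets.load_table1()["rs131654"]
        assert cc.controls.as_tuple() == (572, 1116, 519)
        assert cc.cases.as_tuple() == (274, 669, 375)

    def test_counts_match_generator_bookkeeping(self, snp_rare, snp_common):
        table, truth = simulate_cohort(CohortConfig(n_subjects=500), seed=11)
        cc = tabulate_counts(table, table.snps["snpA"])
        dos = truth["dosage_a"]  # dominant coding: carriage
        status = table.status
        assert cc.cases.n_nn == int(((dos == 0) & (status == 1)).sum())
        assert cc.controls.total + cc.cases.total == 500

    def test_risk_swap_reverses_counts(self, toy_table):
        fwd = tabulate_counts(toy_table, toy_table.snps["snpA"])
        swapped = SnpSpec("snpA", "T", "G", allele_risk="T")
        rev = tabulate_counts(toy_table, swapped)
        assert rev.controls.as_tuple() == fwd.controls.reversed().as_tuple()
        assert rev.cases.as_tuple() == fwd.cases.reversed().as_tuple()


class TestHwe:
    def test_published_control_counts_in_equilibrium(self):
        res = hwe_test(GenotypeCounts(1989, 213, 5), method="chi2")
        # brute-force oracle: q = 223/4414, expected (p^2, 2pq, q^2) * 2207
        q = 223 / 4414
        expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * 2207
        chi2 = float(np.sum((np.array([1989, 213, 5]) - expected) ** 2 / expected))
        assert res.chi_square == pytest.approx(chi2, abs=1e-12)
        assert res.chi_square == pytest.approx(0.0789, abs=5e-4)
        assert res.p_value > 0.05

    def test_perfect_proportions(self):
        res = hwe_test(GenotypeCounts(25, 50, 25), method="chi2")
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_full_enumeration(self):
        from math import factorial
        counts = GenotypeCounts(25, 50, 25)
        n, n_rare = 100, 100
        # oracle: enumerate P(het | allele counts) directly
        probs = {}
        for het in range(n_rare % 2, n_rare + 1, 2):
            hom_r = (n_rare - het) // 2
            hom_c = n - het - hom_r
            probs[het] = (2.0**het) / (
                factorial(hom_r) * factorial(het) * factorial(hom_c))
        z = sum(probs.values())
        p_obs = probs[50] / z
        expected_p = sum(v / z for v in probs.values() if v / z <= p_obs * (1 + 1e-12))
        res = hwe_test(counts, method="exact")
        assert res.p_value == pytest.approx(expected_p, rel=1e-10)

    def test_chi2_invariant_to_risk_relabelling(self):
        a = hwe_test(GenotypeCounts(30, 45, 25), method="chi2")
        b = hwe_test(GenotypeCounts(25, 45, 30), method="chi2")
        assert a.chi_square == pytest.approx(b.chi_square, abs=1e-12)

    def test_monomorphic_is_degenerate(self):
        res = hwe_test(GenotypeCounts(100, 0, 0))
        assert res.degenerate and res.p_value == 1.0

    def test_auto_method_switching(self):
        # expected rr cell ≈ 5.6 ≥ 5 -> chi-square path
        assert hwe_test(GenotypeCounts(1989, 213, 5), method="auto").method == "chi2"
        # expected rr cell ≈ 0.5 < 5 -> exact path
        assert hwe_test(GenotypeCounts(1989, 60, 1), method="auto").method == "exact"

    def test_pvalues_approximately_uniform_under_hwe(self):
        # 200 seeded draws of n=10,000 HWE genotypes at MAF 0.3
        rng = np.random.default_rng(2024)
        maf, n = 0.3, 10_000
        p_geno = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
        rejections = 0
        for _ in range(200):
            counts = rng.multinomial(n, p_geno)
            res = hwe_test(GenotypeCounts(*counts), method="chi2")
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / 200 <= 0.07
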