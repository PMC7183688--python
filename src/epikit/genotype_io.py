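"""Data model and file I/O for biallelic SNPs, genotype counts and subject cohorts.

The central orientation convention throughout the package is the *risk allele*:
the allele more frequent in cases than in controls. It need not be the minor
allele (for *UBE2L3* rs131654 the risk allele T is the major allele), so risk
and minor status are independent attributes of :class:`SnpSpec`. All genotype
counts and dosage codings are expressed in risk-allele orientation: ``nn`` =
zero risk alleles, ``nr`` = one, ``rr`` = two.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist


class GenotypeParseError(ValueError):
    """A genotype or subject record failed validation."""


@dataclass(frozen=True)
class SnpSpec:
    """Identity and allele orientation of one biallelic SNP.

    Parameters
    ----------
    snp_id
        Identifier, e.g. ``"rs2230926"``.
    allele_major, allele_minor
        Single-character alleles; major = more frequent in controls.
    allele_risk
        The allele more frequent in cases than controls. Must be one of the
        two alleles but may be either the major or the minor one.
    """

    snp_id: str
    allele_major: str
    allele_minor: str
    allele_risk: str

    def __post_init__(self) -> None:
        for name in ("allele_major", "allele_minor", "allele_risk"):
            a = getattr(self, name)
            if not (isinstance(a, str) and len(a) == 1):
                raise ValueError(f"{name} must be a single character, got {a!r}")
        if self.allele_major == self.allele_minor:
            raise ValueError(f"{self.snp_id}: major and minor alleles must differ")
        if self.allele_risk not in (self.allele_major, self.allele_minor):
            raise ValueError(
                f"{self.snp_id}: risk allele {self.allele_risk!r} is neither "
                f"{self.allele_major!r} nor {self.allele_minor!r}"
            )

    @property
    def allele_nonrisk(self) -> str:
        return self.allele_minor if self.allele_risk == self.allele_major else self.allele_major

    @property
    def risk_is_minor(self) -> bool:
        return self.allele_risk == self.allele_minor

    def risk_dosage(self, genotype: str) -> int:
        """Number of risk alleles (0/1/2) in an unordered two-character genotype."""
        g = normalize_genotype(genotype, self)
        return sum(1 for a in g if a == self.allele_risk)


def normalize_genotype(genotype: str, snp: SnpSpec) -> str:
    """Validate and canonicalize an unordered allele pair ("TG" ≡ "GT").

    Returns the pair sorted with the non-risk allele first.
    """
    if not isinstance(genotype, str) or len(genotype) != 2:
        raise GenotypeParseError(
            f"{snp.snp_id}: genotype must be a two-character allele pair, got {genotype!r}"
        )
    valid = {snp.allele_major, snp.allele_minor}
    for a in genotype:
        if a not in valid:
            raise GenotypeParseError(
                f"{snp.snp_id}: allele {a!r} not in {sorted(valid)} (genotype {genotype!r})"
            )
    # non-risk first, risk second: "nn", "nr" or "rr" orientation
    return "".join(sorted(genotype, key=lambda a: a == snp.allele_risk))


class CodingScheme(str, enum.Enum):
    """Genotype-to-dosage coding, always in risk-allele orientation."""

    ADDITIVE = "additive"      # nn→0, nr→1, rr→2
    DOMINANT = "dominant"      # carriage: nn→0, nr→1, rr→1
    RECESSIVE = "recessive"    # nn→0, nr→0, rr→1
    GENOTYPE = "genotype"      # 2-df categorical: indicators (nr, rr) vs nn


_CODING_MAP = {
    CodingScheme.ADDITIVE: {0: 0, 1: 1, 2: 2},
    CodingScheme.DOMINANT: {0: 0, 1: 1, 2: 1},
    CodingScheme.RECESSIVE: {0: 0, 1: 0, 2: 1},
}


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts in risk-allele orientation (nn / nr / rr)."""

    n_nn: int
    n_nr: int
    n_rr: int

    def __post_init__(self) -> None:
        for name in ("n_nn", "n_nr", "n_rr"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.n_nn + self.n_nr + self.n_rr

    def reversed(self) -> "GenotypeCounts":
        """Counts under the opposite risk-allele orientation."""
        return GenotypeCounts(self.n_rr, self.n_nr, self.n_nn)

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_nn, self.n_nr, self.n_rr)


@dataclass(frozen=True)
class CaseControlCounts:
    """Per-SNP genotype counts for controls and cases — the unit of all crude statistics."""

    snp: SnpSpec
    controls: GenotypeCounts
    cases: GenotypeCounts


@dataclass(frozen=True)
class HweResult:
    """Hardy-Weinberg equilibrium test result for one group of genotype counts."""

    chi_square: float
    p_value: float
    expected_counts: tuple[float, float, float]
    method: str
    degenerate: bool = False


class SubjectTable:
    """Individual-level cohort: outcome, covariates and one genotype column per SNP.

    Wraps a :class:`pandas.DataFrame` with columns
    ``sample_id, status, age, sex, <snp_id>...``. ``status`` is 0 (control) /
    1 (case); ``sex`` is coded female = 1; genotype cells are unordered
    two-character allele pairs, normalized on construction. ``age``/``sex``
    may be absent if never used as covariates.
    """

    def __init__(self, frame: pd.DataFrame, snp_specs: Sequence[SnpSpec]):
        self.snps: dict[str, SnpSpec] = {s.snp_id: s for s in snp_specs}
        frame = frame.reset_index(drop=True).copy()
        self._validate(frame)
        self.frame = frame

    def _validate(self, frame: pd.DataFrame) -> None:
        required = ["sample_id", "status"]
        for col in required + list(self.snps):
            if col not in frame.columns:
                raise GenotypeParseError(f"missing column {col!r}")
        status = frame["status"]
        if status.isna().any():
            row = int(status.isna().idxmax())
            raise GenotypeParseError(f"row {row}: missing case/control status")
        if not status.isin([0, 1]).all():
            row = int((~status.isin([0, 1])).idxmax())
            raise GenotypeParseError(
                f"row {row}: status must be 0 (control) or 1 (case), got {status[row]!r}"
            )
        frame["status"] = status.astype(int)
        if "age" in frame.columns:
            ok = frame["age"].isna() | (frame["age"] > 0)
            if not ok.all():
                row = int((~ok).idxmax())
                raise GenotypeParseError(f"row {row}: age must be > 0, got {frame['age'][row]!r}")
        for snp_id, spec in self.snps.items():
            col = frame[snp_id]
            normed = []
            for i, g in enumerate(col):
                if g is None or (isinstance(g, float) and np.isnan(g)) or g == "":
                    normed.append(None)  # missing genotype: complete-case per analysis
                    continue
                try:
                    normed.append(normalize_genotype(g, spec))
                except GenotypeParseError as e:
                    raise GenotypeParseError(f"row {i}: {e}") from None
            frame[snp_id] = normed

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def status(self) -> np.ndarray:
        return self.frame["status"].to_numpy()

    def complete_cases(self, snp_ids: Iterable[str]) -> "SubjectTable":
        """Drop subjects missing any of the given genotypes (per-analysis policy)."""
        mask = np.ones(len(self.frame), dtype=bool)
        for sid in snp_ids:
            mask &= self.frame[sid].notna().to_numpy()
        sub = SubjectTable.__new__(SubjectTable)
        sub.snps = self.snps
        sub.frame = self.frame[mask].reset_index(drop=True)
        return sub

    def dosage(self, snp_id: str, scheme: CodingScheme | str = CodingScheme.ADDITIVE) -> np.ndarray:
        """Per-subject dosage under ``scheme``; see :func:`code_genotypes`."""
        return code_genotypes(self, self.snps[snp_id], scheme)

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def read_subject_table(path: str | Path, snp_specs: Sequence[SnpSpec]) -> SubjectTable:
    """Read and validate a subject-level CSV (header ``sample_id,status,age,sex,<snp_id>...``)."""
    frame = pd.read_csv(path, dtype={s.snp_id: "string" for s in snp_specs})
    if "status" in frame.columns:
        bad = pd.to_numeric(frame["status"], errors="coerce")
        if bad.isna().any() or (bad != bad.round()).any():
            row = int((bad.isna() | (bad != bad.round())).idxmax())
            raise GenotypeParseError(f"row {row}: non-integer status {frame['status'][row]!r}")
        frame["status"] = bad.astype(int)
    return SubjectTable(frame, snp_specs)


def read_ped(map_path: str | Path, ped_path: str | Path,
             risk_alleles: dict[str, str] | None = None) -> SubjectTable:
    """Minimal PLINK .ped/.map reader for biallelic SNPs.

    Sex 2 (female) maps to 1, sex 1 (male) to 0; phenotype 2 maps to case,
    1 to control. Major/minor/risk orientation is inferred from allele
    frequencies unless ``risk_alleles`` pins the risk allele per SNP.
    """
    snp_ids = [line.split()[1] for line in Path(map_path).read_text().splitlines() if line.strip()]
    rows = []
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 6 + 2 * len(snp_ids):
            raise GenotypeParseError(
                f".ped row for {f[1] if len(f) > 1 else '?'}: expected "
                f"{6 + 2 * len(snp_ids)} fields, got {len(f)}"
            )
        rec = {"sample_id": f[1], "sex": {"1": 0, "2": 1}.get(f[4]),
               "status": {"1": 0, "2": 1}.get(f[5])}
        if rec["status"] is None:
            raise GenotypeParseError(f".ped row {f[1]}: phenotype must be 1/2, got {f[5]!r}")
        for j, sid in enumerate(snp_ids):
            a1, a2 = f[6 + 2 * j], f[7 + 2 * j]
            rec[sid] = None if "0" in (a1, a2) else a1 + a2
        rows.append(rec)
    frame = pd.DataFrame(rows)
    specs = []
    for sid in snp_ids:
        alleles = sorted({a for g in frame[sid].dropna() for a in g})
        if len(alleles) == 1:
            alleles.append("?")  # monomorphic in file; placeholder minor
        elif len(alleles) > 2:
            raise GenotypeParseError(f"{sid}: more than two alleles {alleles}")
        counts = {a: sum(g.count(a) for g in frame[sid].dropna()) for a in alleles}
        major = max(alleles, key=lambda a: counts.get(a, 0))
        minor = next(a for a in alleles if a != major)
        risk = (risk_alleles or {}).get(sid, minor if minor != "?" else major)
        specs.append(SnpSpec(sid, major, minor, risk))
    return SubjectTable(frame, specs)


def tabulate_counts(table: SubjectTable, snp: SnpSpec) -> CaseControlCounts:
    """Tally genotype counts per group, keyed by risk-allele orientation."""
    sub = table.complete_cases([snp.snp_id])
    dosage = np.array([snp.risk_dosage(g) for g in sub.frame[snp.snp_id]])
    status = sub.status
    def tally(mask: np.ndarray) -> GenotypeCounts:
        d = dosage[mask]
        return GenotypeCounts(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
    return CaseControlCounts(snp=snp, controls=tally(status == 0), cases=tally(status == 1))


def code_genotypes(table: SubjectTable, snp: SnpSpec,
                   scheme: CodingScheme | str) -> np.ndarray:
    """Per-subject risk-allele dosage vector (or 2-column indicators for GENOTYPE).

    Subjects with a missing genotype get NaN; callers drop them per analysis.
    """
    scheme = CodingScheme(scheme)
    raw = np.array(
        [np.nan if g is None else snp.risk_dosage(g) for g in table.frame[snp.snp_id]],
        dtype=float,
    )
    if scheme is CodingScheme.GENOTYPE:
        out = np.column_stack([(raw == 1).astype(float), (raw == 2).astype(float)])
        out[np.isnan(raw)] = np.nan
        return out
    m = _CODING_MAP[scheme]
    return np.array([np.nan if np.isnan(d) else m[int(d)] for d in raw], dtype=float)


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium testing


def hwe_test(counts: GenotypeCounts, method: str = "auto") -> HweResult:
    """Test genotype counts against Hardy-Weinberg proportions.

    ``chi2``: 1-df goodness of fit against expected counts (p², 2pq, q²)·n
    from the observed allele frequency. ``exact``: the conditional
    distribution of the heterozygote count given the allele counts. ``auto``
    uses chi2 when every expected cell is ≥ 5, exact otherwise.

    A monomorphic group (one allele absent) is degenerate: p = 1 by definition.
    """
    n = counts.total
    if n <= 0:
        raise ValueError("hwe_test requires total > 0")
    n_minor = counts.n_nr + 2 * counts.n_rr  # "minor" here = second allele, orientation-free
    q = n_minor / (2 * n)
    p = 1.0 - q
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    if q == 0.0 or q == 1.0:
        return HweResult(0.0, 1.0, expected, method="degenerate", degenerate=True)

    if method == "auto":
        method = "chi2" if min(expected) >= 5 else "exact"
    if method == "chi2":
        obs = counts.as_tuple()
        stat = float(sum((o - e) ** 2 / e for o, e in zip(obs, expected)))
        pval = float(chi2_dist.sf(stat, df=1))
        return HweResult(stat, min(pval, 1.0), expected, method="chi2")
    if method == "exact":
        pval = _hwe_exact_p(counts)
        obs = counts.as_tuple()
        stat = float(sum((o - e) ** 2 / e for o, e in zip(obs, expected)))
        return HweResult(stat, pval, expected, method="exact")
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact_p(counts: GenotypeCounts) -> float:
    """Exact HWE p: conditional probability of heterozygote counts as or less
    likely than observed, given the allele counts."""
    n = counts.total
    n_rare = min(counts.n_nr + 2 * counts.n_rr, counts.n_nr + 2 * counts.n_nn)
    het_obs = counts.n_nr
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # P(het | n, n_rare) ∝ n! / (hom1! het! hom2!) * 2^het ; normalized below
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == het_obs][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Counts CSV dialect: snp_id,group,n_nn,n_nr,n_rr with group in {case, control}


def write_counts_csv(path: str | Path, counts: Iterable[CaseControlCounts]) -> None:
    rows = []
    for cc in counts:
        for group, g in (("control", cc.controls), ("case", cc.cases)):
            rows.append({"snp_id": cc.snp.snp_id, "group": group,
                         "n_nn": g.n_nn, "n_nr": g.n_nr, "n_rr": g.n_rr})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_counts_csv(path: str | Path, snp_specs: Sequence[SnpSpec]) -> list[CaseControlCounts]:
    frame = pd.read_csv(path)
    specs = {s.snp_id: s for s in snp_specs}
    out = []
    for sid, grp in frame.groupby("snp_id", sort=False):
        if sid not in specs:
            raise GenotypeParseError(f"counts file references unknown SNP {sid!r}")
        by_group = {}
        for _, row in grp.iterrows():
            by_group[row["group"]] = GenotypeCounts(
                int(row["n_nn"]), int(row["n_nr"]), int(row["n_rr"])
            )
        if set(by_group) != {"case", "control"}:
            raise GenotypeParseError(f"{sid}: need one 'case' and one 'control' row")
        out.append(CaseControlCounts(specs[sid], by_group["control"], by_group["case"]))
    return out
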