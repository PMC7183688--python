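"""Synthetic-data generators with known ground truth for every pipeline input.

Three generators mirror the three data layers of the analysis:

- :func:`simulate_cohort` — case-control genotypes and covariates. Genotypes
  are drawn per SNP under Hardy-Weinberg proportions at a configured minor-
  allele frequency (the two loci are independent — no linkage disequilibrium);
  disease status is Bernoulli with
  logit P(case) = β0 + β1·A + β2·B + β3·AB + β_age·age + β_sex·sex,
  where A and B are the coded dosages (default: carriage for the rare SNP,
  additive for the common SNP). Defaults reproduce the scale of a 3525-subject
  lupus case-control study: MAFs 0.05 / 0.48, OR1 = 1.9, OR2 = 1.2,
  OR_int = 1.6, ≈ 37% cases, cases younger and more often female than controls.
- :func:`simulate_expression` — per-allele additive eQTL effect plus group
  offsets (an ethnicity-like categorical confounder) and Gaussian noise.
- :func:`simulate_qpcr` — four-condition knockdown qPCR Ct values whose
  ΔCt structure encodes configured fold effects and a synergy multiplier.

Randomness is split into named substreams from the master seed (genotypes,
covariates, outcomes), so e.g. adding covariates never shifts genotype draws.
Same seed + config ⇒ bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .genotype_io import CodingScheme, SnpSpec, SubjectTable
from .synergy import AUGMENT, COMBINED, CONDITIONS, REDUCTION, REFERENCE

#: default SNP pair mimicking a rare-risk-minor / common-risk-major design
SNP_A = SnpSpec("snpA", allele_major="T", allele_minor="G", allele_risk="G")
SNP_B = SnpSpec("snpB", allele_major="T", allele_minor="G", allele_risk="T")


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 3525
    maf_a: float = 0.05
    maf_b: float = 0.48
    beta0: float = -0.66          # baseline log-odds; gives ≈ 37% cases at defaults
    beta1: float = float(np.log(1.9))   # SNP-A main effect (log OR)
    beta2: float = float(np.log(1.2))   # SNP-B main effect
    beta3: float = float(np.log(1.6))   # interaction (log OR_int)
    beta_age: float = -0.03       # per year; cases younger
    beta_sex: float = 1.2         # female = 1; cases more often female
    age_mean: float = 38.0
    age_sd: float = 15.0
    female_fraction: float = 0.83
    coding_a: CodingScheme = CodingScheme.DOMINANT
    coding_b: CodingScheme = CodingScheme.ADDITIVE
    snp_a: SnpSpec = SNP_A
    snp_b: SnpSpec = SNP_B
    n_cases: int | None = None      # optional fixed case/control subsample
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for m in (self.maf_a, self.maf_b):
            if not (0.0 < m <= 0.5):
                raise ValueError(f"MAF must be in (0, 0.5], got {m}")


@dataclass(frozen=True)
class ExpressionConfig:
    n_samples: int = 600
    effect: float = -0.5          # expression change per risk allele
    residual_sd: float = 1.0
    intercept: float = 10.0
    maf: float = 0.3
    group_offsets: tuple[float, ...] = (0.0, 0.6, -0.4, 1.0)  # ethnicity-like groups
    gene_id: str = "gene1"
    snp_id: str = "snp1"

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")


@dataclass(frozen=True)
class QpcrConfig:
    genes: tuple[str, ...] = ("CCL2", "CXCL8", "IL6")
    timepoints: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0)
    reduction_fold: float = 2.0   # both-knockdown vs reference, at t > 0
    augment_fold: float = 2.0     # no-knockdown vs reference, at t > 0
    synergy: Mapping[tuple[str, float], float] | float = 1.0
    n_samples: int = 3            # biological replicates
    n_tech: int = 3               # technical qPCR replicates per sample
    ct_sd: float = 0.15           # per-measurement Ct noise
    hk_ct: float = 18.0           # housekeeping-gene baseline Ct
    base_delta_ct: float = 8.0    # reference-condition ΔCt

    def synergy_at(self, gene: str, timepoint: float) -> float:
        if isinstance(self.synergy, Mapping):
            return float(self.synergy.get((gene, float(timepoint)), 1.0))
        return float(self.synergy)


def _hwe_genotypes(rng: np.random.Generator, n: int, snp: SnpSpec, maf: float) -> list[str]:
    p_geno = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    minor_count = rng.choice(3, size=n, p=p_geno)
    genos = {0: snp.allele_major * 2,
             1: snp.allele_major + snp.allele_minor,
             2: snp.allele_minor * 2}
    return [genos[int(k)] for k in minor_count]


def simulate_cohort(config: CohortConfig, seed: int) -> tuple[SubjectTable, dict]:
    """Draw a cohort and return it with a ground-truth record.

    The truth record holds the generating coefficients, the coded dosages and
    the per-subject case probabilities, so recovery tests can compare against
    exactly what generated the data.
    """
    ss = np.random.SeedSequence(seed)
    rng_geno, rng_cov, rng_out = (np.random.default_rng(s) for s in ss.spawn(3))
    n = config.n_subjects
    geno_a = _hwe_genotypes(rng_geno, n, config.snp_a, config.maf_a)
    geno_b = _hwe_genotypes(rng_geno, n, config.snp_b, config.maf_b)
    age = np.clip(rng_cov.normal(config.age_mean, config.age_sd, n), 18.0, 90.0)
    sex = (rng_cov.random(n) < config.female_fraction).astype(int)

    frame = pd.DataFrame({
        "sample_id": [f"S{i:05d}" for i in range(n)],
        "status": 0,
        "age": np.round(age, 1),
        "sex": sex,
        config.snp_a.snp_id: geno_a,
        config.snp_b.snp_id: geno_b,
    })
    table = SubjectTable(frame, [config.snp_a, config.snp_b])
    dos_a = table.dosage(config.snp_a.snp_id, config.coding_a)
    dos_b = table.dosage(config.snp_b.snp_id, config.coding_b)
    eta = (config.beta0 + config.beta1 * dos_a + config.beta2 * dos_b
           + config.beta3 * dos_a * dos_b
           + config.beta_age * table.frame["age"].to_numpy()
           + config.beta_sex * sex)
    prob = 1.0 / (1.0 + np.exp(-eta))
    status = (rng_out.random(n) < prob).astype(int)
    table.frame["status"] = status

    if config.n_cases is not None or config.n_controls is not None:
        table = _subsample(table, config.n_cases, config.n_controls, rng_out)
    if table.status.sum() < 10:
        import warnings
        warnings.warn(f"only {int(table.status.sum())} cases simulated; "
                      "estimates will be unstable", stacklevel=2)
    truth = {
        "config": config,
        "beta": {"beta0": config.beta0, "beta1": config.beta1,
                 "beta2": config.beta2, "beta3": config.beta3,
                 "beta_age": config.beta_age, "beta_sex": config.beta_sex},
        "dosage_a": dos_a, "dosage_b": dos_b, "probability": prob,
    }
    return table, truth


def _subsample(table: SubjectTable, n_cases: int | None, n_controls: int | None,
               rng: np.random.Generator) -> SubjectTable:
    status = table.status
    keep = []
    for value, want in ((1, n_cases), (0, n_controls)):
        idx = np.flatnonzero(status == value)
        if want is None:
            keep.append(idx)
        else:
            if want > idx.size:
                raise ValueError(f"requested {want} subjects with status {value}, "
                                 f"only {idx.size} simulated")
            keep.append(rng.choice(idx, size=want, replace=False))
    keep_idx = np.sort(np.concatenate(keep))
    sub = SubjectTable.__new__(SubjectTable)
    sub.snps = table.snps
    sub.frame = table.frame.iloc[keep_idx].reset_index(drop=True)
    return sub


def simulate_expression(config: ExpressionConfig, seed: int,
                        dosage: np.ndarray | None = None):
    """Expression = intercept + effect·dosage + group offset + N(0, sd²).

    Returns ``(ExpressionMatrix, dosage, groups)`` with one gene row; sample
    ids are s0000, s0001, ...
    """
    from .eqtl import ExpressionMatrix

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = config.n_samples
    if dosage is None:
        maf = config.maf
        p_geno = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        dosage = rng.choice(3, size=n, p=p_geno).astype(float)
    else:
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (n,):
            raise ValueError("dosage length must equal n_samples")
    n_groups = len(config.group_offsets)
    groups = rng.integers(0, n_groups, size=n)
    offsets = np.asarray(config.group_offsets)[groups]
    y = (config.intercept + config.effect * dosage + offsets
         + rng.normal(0.0, config.residual_sd, n))
    sample_ids = [f"s{i:04d}" for i in range(n)]
    matrix = ExpressionMatrix(pd.DataFrame([y], index=[config.gene_id], columns=sample_ids))
    group_labels = pd.Series([f"g{g}" for g in groups], index=sample_ids)
    dosage_frame = pd.DataFrame({config.snp_id: dosage}, index=pd.Index(sample_ids, name="sample_id"))
    return matrix, dosage_frame, group_labels


def simulate_qpcr(config: QpcrConfig, seed: int) -> pd.DataFrame:
    """Long-format qPCR records whose ΔCt encodes the configured fold effects.

    At t = 0 (pre-stimulation) all conditions sit at fold 1. For t > 0 the
    true folds versus the reference are ``reduction_fold``, ``augment_fold``
    and ``reduction_fold × augment_fold × synergy(gene, t)``; each of the
    n_samples × n_tech measurements gets independent Gaussian Ct noise on
    both the target and the housekeeping channel.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for gene in config.genes:
        for tp in config.timepoints:
            if tp > 0:
                folds = {
                    REFERENCE: 1.0,
                    REDUCTION: config.reduction_fold,
                    AUGMENT: config.augment_fold,
                    COMBINED: (config.reduction_fold * config.augment_fold
                               * config.synergy_at(gene, tp)),
                }
            else:
                folds = {c: 1.0 for c in CONDITIONS}
            for cond in CONDITIONS:
                true_dct = config.base_delta_ct - np.log2(folds[cond])
                rep = 0
                for _ in range(config.n_samples):
                    for _ in range(config.n_tech):
                        ct_hk = config.hk_ct + rng.normal(0.0, config.ct_sd)
                        ct_tg = config.hk_ct + true_dct + rng.normal(0.0, config.ct_sd)
                        rows.append({
                            "condition": cond, "gene": gene, "timepoint_h": tp,
                            "replicate": rep, "ct_target": round(float(ct_tg), 4),
                            "ct_gapdh": round(float(ct_hk), 4),
                        })
                        rep += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# YAML config loading (documented schema: flat key-value per generator)


def _load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def load_cohort_config(path: str | Path) -> CohortConfig:
    data = _load_yaml(path)
    for key in ("coding_a", "coding_b"):
        if key in data:
            data[key] = CodingScheme(data[key])
    for key in ("snp_a", "snp_b"):
        if key in data:
            data[key] = SnpSpec(**data[key])
    return CohortConfig(**data)


def load_expression_config(path: str | Path) -> ExpressionConfig:
    data = _load_yaml(path)
    if "group_offsets" in data:
        data["group_offsets"] = tuple(data["group_offsets"])
    return ExpressionConfig(**data)


def load_qpcr_config(path: str | Path) -> QpcrConfig:
    data = _load_yaml(path)
    for key in ("genes", "timepoints"):
        if key in data:
            data[key] = tuple(data[key])
    if isinstance(data.get("synergy"), dict):
        data["synergy"] = {
            (gene, float(tp)): float(v)
            for (gene, tps) in data["synergy"].items()
            for tp, v in tps.items()
        }
    return QpcrConfig(**data)
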