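"""Bundled genotype-count fixtures from a Korean SLE case-control study.

The counts are the published genotype distributions of 2207 healthy controls
and 1318 systemic lupus erythematosus patients at two SNPs: *TNFAIP3*
rs2230926 (T>G; the risk allele G is the minor allele) and *UBE2L3* rs131654
(T>G; the risk allele T is the MAJOR allele), plus the six-cell
carriage × genotype stratified table of their joint distribution. The
published odds ratios alongside are age- and sex-adjusted logistic estimates;
they cannot be recomputed exactly from counts alone (the individual-level
covariates are not public), so this module exposes them as reference values
for side-by-side reporting, never as recomputed output.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .genotype_io import CaseControlCounts, SnpSpec, read_counts_csv
from .interaction import StratifiedEpistasisTable, StratumCell

RS2230926 = SnpSpec("rs2230926", allele_major="T", allele_minor="G", allele_risk="G")
RS131654 = SnpSpec("rs131654", allele_major="T", allele_minor="G", allele_risk="T")

N_CONTROLS = 2207
N_CASES = 1318

#: published age/sex-adjusted single-SNP estimates: OR, (CI low, CI high), p
PUBLISHED_SNP_ESTIMATES = {
    "rs2230926": {"or": 1.9, "ci": (1.6, 2.4), "p": 8.8e-11},
    "rs131654": {"or": 1.2, "ci": (1.1, 1.4), "p": 1.1e-4},
}

#: published age/sex-adjusted stratum ORs versus the (N, nn) reference
PUBLISHED_STRATUM_ORS = {
    ("N", "nr"): 1.2,
    ("N", "rr"): 1.3,
    ("R", "nn"): 1.3,
    ("R", "nr"): 2.3,
    ("R", "rr"): 4.1,
}

#: published OR_int values computed from the adjusted stratum ORs
PUBLISHED_OR_INT = {("R", "rr"): 2.4, ("R", "nr"): 1.5}

#: published regression interaction estimate and additive-scale panel
PUBLISHED_REGRESSION_OR_INT = {"or_int": 1.6, "p": 0.0028}
PUBLISHED_AP = {"ap": 0.42, "ci": (0.18, 0.66), "p": 0.049}

_CHECKSUMS = {
    "table1_counts.csv": "efc0c41e272adc4323442fc0508c43664cf379a391490f25275c9ca9420d642c",
    "table2_strata.csv": "3ea419f2f16b6818a67aaf1f858da85b30eaef510cb600ac948e150e4ba7790a",
}


class FixtureIntegrityError(RuntimeError):
    """A bundled fixture file does not match its recorded checksum."""


def _fixture_path(name: str):
    path = resources.files("epikit.data") / name
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(
            f"{name}: checksum {digest} != expected {_CHECKSUMS[name]}"
        )
    return path


def load_table1() -> dict[str, CaseControlCounts]:
    """Single-SNP case/control genotype counts, keyed by SNP id."""
    with resources.as_file(_fixture_path("table1_counts.csv")) as p:
        counts = read_counts_csv(p, [RS2230926, RS131654])
    return {cc.snp.snp_id: cc for cc in counts}


def load_table2() -> StratifiedEpistasisTable:
    """Six-cell carriage (rs2230926) × genotype (rs131654) stratified counts."""
    with resources.as_file(_fixture_path("table2_strata.csv")) as p:
        frame = pd.read_csv(p)
    cells = {
        (row["snpA_level"], row["snpB_level"]): StratumCell(
            controls=int(row["controls"]), cases=int(row["cases"])
        )
        for _, row in frame.iterrows()
    }
    return StratifiedEpistasisTable(cells)
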