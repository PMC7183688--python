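"""Orchestration: fixture-based table reproduction and simulation studies.

Two entry points drive everything the analysis scripts and the acceptance
script need:

- :func:`reproduce_tables` recomputes every crude statistic the bundled
  genotype-count fixtures support (crude ORs, HWE, stratified OR_int on both
  crude and published-adjusted ORs, the additive-interaction panel,
  Bonferroni thresholds) and reports them side by side with the published
  adjusted values, which need unavailable individual-level covariates and are
  therefore labelled, never recomputed.
- :func:`run_calibration` runs the Monte-Carlo studies (type-I error of the
  Wald interaction test, power, AP confidence-interval coverage, parameter
  recovery) on synthetic cohorts with known truth.

Every run can write its outputs plus a :class:`RunManifest` so that re-running
with the manifest's seed reproduces the outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .association import bonferroni, crude_or_2x2, AssociationEstimate
from .genotype_io import CaseControlCounts, CodingScheme, hwe_test
from .interaction import (
    additive_from_logistic,
    or_int_from_ors,
    regression_or_int,
    rothman_additive,
    stratified_or_int,
)
from .simulate import CohortConfig, simulate_cohort

__version__ = "0.1.0"


@dataclass(frozen=True)
class RunManifest:
    command: str
    config_hash: str
    seed: int | None
    package_version: str
    timestamp: str
    outputs: tuple[str, ...]

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _manifest(out_dir: Path, command: str, config, seed, outputs: list[Path]) -> None:
    digest = hashlib.sha256(repr(config).encode()).hexdigest()[:16]
    m = RunManifest(
        command=command, config_hash=digest, seed=seed,
        package_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        outputs=tuple(str(p.name) for p in outputs),
    )
    m.write(out_dir / f"{command}_manifest.json")


def crude_or_from_counts(cc: CaseControlCounts, mode: str = "carriage") -> AssociationEstimate:
    """Crude single-SNP OR from genotype counts.

    ``carriage``: risk-allele carriers vs non-carriers (the natural crude
    comparator for a rare variant). ``allelic``: risk vs non-risk allele
    counts (2n alleles; the crude per-allele comparator for a common
    variant). ``recessive``: risk homozygotes vs the rest.
    """
    ctl, cas = cc.controls, cc.cases
    if mode == "carriage":
        return crude_or_2x2(cas.n_nr + cas.n_rr, cas.n_nn, ctl.n_nr + ctl.n_rr, ctl.n_nn)
    if mode == "allelic":
        return crude_or_2x2(cas.n_nr + 2 * cas.n_rr, 2 * cas.n_nn + cas.n_nr,
                            ctl.n_nr + 2 * ctl.n_rr, 2 * ctl.n_nn + ctl.n_nr)
    if mode == "recessive":
        return crude_or_2x2(cas.n_rr, cas.n_nn + cas.n_nr, ctl.n_rr, ctl.n_nn + ctl.n_nr)
    raise ValueError(f"unknown crude OR mode {mode!r}")


#: crude comparator per fixture SNP: carriage for the rare variant,
#: per-allele for the common one (mirroring how each is analysed downstream)
CRUDE_MODE = {"rs2230926": "carriage", "rs131654": "allelic"}


def reproduce_tables(out_dir: str | Path | None = None) -> dict:
    """Recompute all fixture-supported statistics; optionally write reports.

    Returns a dict with keys ``table1`` (per-SNP crude ORs and HWE alongside
    published adjusted values), ``table2`` (stratified report),
    ``worked_or_int`` (OR_int from the published adjusted stratum ORs),
    ``crude_or_int`` (OR_int from crude stratum ORs), ``additive``
    (RERI/AP/S panel), ``bonferroni`` and ``integrity``.
    """
    table1 = datasets.load_table1()
    table2 = datasets.load_table2()

    rows = []
    hwe = {}
    for snp_id, cc in table1.items():
        est = crude_or_from_counts(cc, CRUDE_MODE[snp_id])
        h = hwe_test(cc.controls, method="chi2")
        hwe[snp_id] = h
        pub = datasets.PUBLISHED_SNP_ESTIMATES[snp_id]
        rows.append({
            "snp_id": snp_id,
            "controls_nn_nr_rr": "/".join(map(str, cc.controls.as_tuple())),
            "cases_nn_nr_rr": "/".join(map(str, cc.cases.as_tuple())),
            "crude_mode": CRUDE_MODE[snp_id],
            "crude_or": est.odds_ratio,
            "crude_ci_low": est.ci_low,
            "crude_ci_high": est.ci_high,
            "crude_p": est.p_value,
            "published_adjusted_or": pub["or"],
            "published_p": pub["p"],
            "hwe_chi2_controls": h.chi_square,
            "hwe_p_controls": h.p_value,
        })
    table1_report = pd.DataFrame(rows)

    crude_ors = table2.crude_ors()
    strata_rows = []
    for key in table2.keys:
        cell = table2.cells[key]
        row = {"stratum": f"{key[0]}/{key[1]}", "controls": cell.controls,
               "cases": cell.cases}
        if key == table2.reference:
            row["crude_or"] = 1.0
            row["published_adjusted_or"] = 1.0
        else:
            row["crude_or"] = crude_ors[key].odds_ratio
            row["published_adjusted_or"] = datasets.PUBLISHED_STRATUM_ORS[key]
        strata_rows.append(row)
    table2_report = pd.DataFrame(strata_rows)

    pub = datasets.PUBLISHED_STRATUM_ORS
    worked = {
        ("R", "rr"): or_int_from_ors(pub[("R", "rr")], pub[("R", "nn")], pub[("N", "rr")]),
        ("R", "nr"): or_int_from_ors(pub[("R", "nr")], pub[("R", "nn")], pub[("N", "nr")]),
    }
    crude_int = {
        ("R", "rr"): stratified_or_int(table2, ("R", "rr"), ("R", "nn"), ("N", "rr")),
        ("R", "nr"): stratified_or_int(table2, ("R", "nr"), ("R", "nn"), ("N", "nr")),
    }
    additive = {
        "from_published_ors": rothman_additive(
            pub[("R", "nn")], pub[("N", "rr")], pub[("R", "rr")]),
        "from_crude_ors": rothman_additive(
            crude_ors[("R", "nn")].odds_ratio,
            crude_ors[("N", "rr")].odds_ratio,
            crude_ors[("R", "rr")].odds_ratio),
        "published_ap": datasets.PUBLISHED_AP,
    }

    mt = bonferroni([datasets.PUBLISHED_SNP_ESTIMATES[s]["p"] for s in table1], 0.05)

    integrity = {
        "table1_controls_total": {cc.snp.snp_id: cc.controls.total for cc in table1.values()},
        "table1_cases_total": {cc.snp.snp_id: cc.cases.total for cc in table1.values()},
        "table2_controls_total": table2.total_controls(),
        "table2_cases_total": table2.total_cases(),
        "table2_N_controls": sum(
            table2.cells[("N", b)].controls for b in ("nn", "nr", "rr")),
        "expected_controls": datasets.N_CONTROLS,
        "expected_cases": datasets.N_CASES,
    }

    result = {
        "table1": table1_report, "table2": table2_report, "hwe": hwe,
        "worked_or_int": worked, "crude_or_int": crude_int,
        "additive": additive, "bonferroni": mt, "integrity": integrity,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        outputs = []
        for name, frame in (("table1_report.tsv", table1_report),
                            ("table2_report.tsv", table2_report)):
            path = out_dir / name
            frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
            outputs.append(path)
        panel = out_dir / "interaction_panel.tsv"
        with open(panel, "w") as fh:
            fh.write("quantity\tvalue\tnote\n")
            for key, est in worked.items():
                fh.write(f"or_int_published_{key[0]}_{key[1]}\t{est.or_int:.1f}\t"
                         "from published adjusted stratum ORs\n")
            for key, est in crude_int.items():
                fh.write(f"or_int_crude_{key[0]}_{key[1]}\t{est.or_int:.4f}\t"
                         "from crude stratum ORs (unadjusted)\n")
            add = additive["from_published_ors"]
            fh.write(f"reri_published_ors\t{add.reri:.4f}\tOR approximates RR\n")
            fh.write(f"ap_published_ors\t{add.ap:.4f}\tOR approximates RR\n")
            fh.write(f"bonferroni_threshold\t{mt.alpha_per_test}\tfamily alpha 0.05, m=2\n")
        outputs.append(panel)
        _manifest(out_dir, "reproduce", "fixtures-v1", None, outputs)
    return result


# ---------------------------------------------------------------------------
# Simulation studies

#: type-I / power study conditions: the common-variant MAF matches the study
#: scale; the rarer variant is kept at MAF 0.20 so the interaction cell stays
#: large enough for Wald asymptotics at n = 2000
TYPE1_CONFIG = CohortConfig(n_subjects=2000, maf_a=0.20, maf_b=0.48,
                            beta3=0.0)
POWER_CONFIG = CohortConfig()  # study scale: n=3525, OR_int = 1.6

#: AP-coverage study: dominant × dominant so the three joint/single ORs are
#: plain coefficients; no covariates (they are not part of the estimand)
AP_CONFIG = CohortConfig(
    n_subjects=2000, maf_a=0.3, maf_b=0.3,
    beta0=-1.5, beta1=float(np.log(1.5)), beta2=float(np.log(1.5)),
    beta3=float(np.log(1.3)), beta_age=0.0, beta_sex=0.0,
    coding_a=CodingScheme.DOMINANT, coding_b=CodingScheme.DOMINANT,
)

RECOVERY_CONFIG = CohortConfig()  # OR1=1.9, OR2=1.2, OR_int=1.6 at n=3525


def true_ap(config: CohortConfig) -> float:
    """The additive-interaction estimand implied by the generating ORs."""
    rr10, rr01 = np.exp(config.beta1), np.exp(config.beta2)
    rr11 = np.exp(config.beta1 + config.beta2 + config.beta3)
    return float((rr11 - rr10 - rr01 + 1.0) / rr11)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    # uint32 child seeds, kept below 2**31
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def run_calibration(study: str, seed: int, n_replicates: int | None = None,
                    config: CohortConfig | None = None,
                    out_dir: str | Path | None = None) -> pd.DataFrame:
    """Replicate-loop Monte-Carlo study; returns a one-row summary frame.

    Studies: ``type1`` (null interaction rejection rate), ``power``
    (rejection rate at the generating OR_int), ``ap_coverage`` (delta-method
    95% CI coverage of the true AP), ``recovery`` (mean recovered ORs).
    Summaries carry Monte-Carlo standard errors.
    """
    defaults = {"type1": (TYPE1_CONFIG, 500), "power": (POWER_CONFIG, 200),
                "ap_coverage": (AP_CONFIG, 500), "recovery": (RECOVERY_CONFIG, 200)}
    if study not in defaults:
        raise ValueError(f"unknown study {study!r}; choose from {sorted(defaults)}")
    default_cfg, default_reps = defaults[study]
    cfg = config if config is not None else default_cfg
    reps = n_replicates if n_replicates is not None else default_reps
    seeds = _child_seeds(seed, reps)

    if study in ("type1", "power"):
        rejected = np.empty(reps, dtype=bool)
        for i, s in enumerate(seeds):
            table, _ = simulate_cohort(cfg, int(s))
            est, _ = regression_or_int(table, cfg.snp_a, cfg.snp_b,
                                       cfg.coding_a, cfg.coding_b,
                                       covariates=("age", "sex"))
            rejected[i] = est.p_value < 0.05
        rate = float(rejected.mean())
        mc_se = float(np.sqrt(rate * (1 - rate) / reps))
        summary = pd.DataFrame([{
            "study": study, "n_replicates": reps, "n_subjects": cfg.n_subjects,
            "true_or_int": float(np.exp(cfg.beta3)),
            "rejection_rate": rate, "mc_se": mc_se,
        }])
    elif study == "ap_coverage":
        target = true_ap(cfg)
        covered = np.empty(reps, dtype=bool)
        ap_hat = np.empty(reps)
        for i, s in enumerate(seeds):
            table, _ = simulate_cohort(cfg, int(s))
            _, fit = regression_or_int(table, cfg.snp_a, cfg.snp_b,
                                       cfg.coding_a, cfg.coding_b)
            add = additive_from_logistic(fit, "snp_a", "snp_b", "snp_a_x_snp_b")
            ap_hat[i] = add.ap
            covered[i] = add.ap_ci_low <= target <= add.ap_ci_high
        rate = float(covered.mean())
        summary = pd.DataFrame([{
            "study": study, "n_replicates": reps, "n_subjects": cfg.n_subjects,
            "true_ap": target, "mean_ap_hat": float(ap_hat.mean()),
            "coverage": rate,
            "mc_se": float(np.sqrt(rate * (1 - rate) / reps)),
        }])
    else:  # recovery
        betas = np.empty((reps, 3))
        for i, s in enumerate(seeds):
            table, _ = simulate_cohort(cfg, int(s))
            _, fit = regression_or_int(table, cfg.snp_a, cfg.snp_b,
                                       cfg.coding_a, cfg.coding_b,
                                       covariates=("age", "sex"))
            c = fit.coefficients
            betas[i] = (c["snp_a"], c["snp_b"], c["snp_a_x_snp_b"])
        mean_b = betas.mean(axis=0)
        se_b = betas.std(axis=0, ddof=1) / np.sqrt(reps)
        summary = pd.DataFrame([{
            "study": study, "n_replicates": reps, "n_subjects": cfg.n_subjects,
            "true_or1": float(np.exp(cfg.beta1)),
            "true_or2": float(np.exp(cfg.beta2)),
            "true_or_int": float(np.exp(cfg.beta3)),
            "recovered_or1": float(np.exp(mean_b[0])),
            "recovered_or2": float(np.exp(mean_b[1])),
            "recovered_or_int": float(np.exp(mean_b[2])),
            "mc_se_log_or1": float(se_b[0]),
            "mc_se_log_or2": float(se_b[1]),
            "mc_se_log_or_int": float(se_b[2]),
        }])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"calibration_{study}.tsv"
        summary.to_csv(path, sep="\t", index=False, float_format="%.6g")
        _manifest(out_dir, f"calibrate_{study}", cfg, seed, [path])
    return summary
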