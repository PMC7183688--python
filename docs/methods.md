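# Methods

## Study design and orientation conventions

The package models a two-SNP case-control epistasis analysis. Everything is
expressed in **risk-allele orientation**: the risk allele is the one more
frequent in cases than controls, independently of minor/major status (the
bundled fixtures include one SNP whose risk allele is the major allele, so
the two attributes are never conflated). Genotype strings are unordered
("TG" ≡ "GT"); phase is never used. Counts are always (nn, nr, rr) = zero,
one, two risk alleles. Dosage codings: additive {0,1,2}, dominant/carriage
{0,1,1}, recessive {0,0,1}, and a 2-df genotype coding (nr, rr indicators
against nn).

Missing genotypes are dropped per analysis (complete-case for the SNPs that
analysis uses), never imputed. Sex is coded female = 1; this affects only
the sign of the sex coefficient.

## Hardy-Weinberg testing

The default χ² test compares observed genotype counts with (p², 2pq, q²)·n
at the observed allele frequency, 1 df. When any expected cell is below 5
the exact test is used instead: the conditional distribution of the
heterozygote count given the allele counts, with the p-value summing all
outcomes at most as probable as the observed one. A monomorphic group is
returned as a flagged degenerate result with p = 1 rather than an error, so
batch scans do not abort on fixed sites.

## Logistic regression (IRLS)

The in-package fitter is plain Newton/IRLS: start at β = 0, update
β ← β + (XᵀWX)⁻¹Xᵀ(y − μ) with W = diag(μ(1−μ)), step-halving whenever a
step would decrease the log-likelihood. Convergence is declared when the
largest score component falls below 1e-8; a likelihood-stall exit exists but
its tolerance (1e-13 relative) sits at the double-precision noise floor, so
the score criterion governs ordinary fits and Newton's quadratic convergence
delivers coefficients accurate to ~1e-10 — tight enough that a saturated fit
on a 2×2×2 table reproduces the four-cell cross-ratio to 1e-8. Covariance is
the inverse observed information at the optimum. Suspected separation
(|β| > 15, far beyond any plausible odds ratio on these scales) is flagged
as non-converged with a message instead of silently returning diverged
estimates; no Firth-type correction is applied. Zero cells in crude 2×2
tables get the Haldane–Anscombe +0.5 correction, flagged in the output.

## Interaction measures

*Multiplicative.* OR_int = OR_1&2/(OR_1 × OR_2), equal to exp(β3) in the
product-term model. The regression default codes the rare SNP as carriage
and the common SNP as additive dosage, mirroring the stratified table; both
codings are configurable. The stratified route computes each stratum's OR
against the (N, nn) reference — crude from counts, or adjusted from one
genotype-categorical logistic fit (an indicator per non-reference stratum
plus covariates) when subject-level data are available. A worked-example
mode accepts pre-computed (e.g. published, adjusted) ORs directly; report
rounding is one decimal, with OR_int recomputed from rounded ORs only in
that mode.

*Additive.* RERI = RR11 − RR10 − RR01 + 1, AP = RERI/RR11,
S = (RR11−1)/((RR10−1)+(RR01−1)). This is the standard three-term AP; a
two-term variant (omitting RR01) circulates in the applied literature but is
inconsistent with the additive null RR11 = RR10 + RR01 − 1, under which AP
must be 0, so the standard form is implemented. ORs approximate RRs under
the rare-disease assumption, and every estimate carries an explicit flag
saying so. The AP delta-method CI uses the gradient
(−RR10/RR11, −RR01/RR11, (RR10+RR01−1)/RR11) with respect to the log-RRs;
when the three log-RRs come from one logistic fit, their covariance is the
linear transform AΣAᵀ of the coefficient covariance, so the CI accounts for
the correlation among the estimates. S is undefined and returned as None
when both single-exposure RRs equal 1.

## eQTL model

Ordinary least squares of one gene's expression on risk-allele dosage with
an optional unordered categorical covariate (one-hot columns against the
lexicographically first level; every level needs ≥ 2 samples). The dosage
slope is tested two-sided on n − p residual df. Expression values are used
as supplied — normalization and transformation are upstream concerns. The
batch scan applies no multiple-testing correction because its intended use
is a handful of pre-specified gene-SNP pairs.

## ΔΔCt synergy

ΔCt = Ct_target − Ct_housekeeping per measurement; ΔΔCt = mean ΔCt(condition)
− mean ΔCt(reference); fold = 2^(−ΔΔCt), i.e. amplification efficiency fixed
at 2 with no standard-curve correction. Replicate ΔCt values are averaged
within condition before differencing (the usual Livak convention), while the
per-replicate ΔCt values feed Welch two-sample t-tests — testing on the Ct
scale because it is variance-stabilized relative to folds; Welch rather than
pooled because equal variances across knockdown conditions is not a safe
assumption. The condition mapping is: reference = high-suppressor/low-enhancer;
reduction effect = both-low vs reference; augment effect = both-high vs
reference; combined = low-suppressor/high-enhancer vs reference;
ŝ = combined ÷ (reduction × augment). Star thresholds are inclusive
(p ≤ 0.05/0.01/0.001/0.0001). Zero-variance cells (possible in noiseless
simulations) skip the t-test with a warning; folds are still reported.

A note on invariances: ŝ is invariant to global Ct shifts and to shifts of
the housekeeping channel (they cancel in ΔΔCt), but *not* to multiplying all
three folds by a common factor — ŝ = c/(r·a) scales by 1/k under that
operation, so only the Ct-shift form is asserted as a property.

## Synthetic-data generators

The cohort generator runs the disease model forward: independent HWE
genotypes per SNP (no linkage disequilibrium — the two loci sit on different
chromosomes in the motivating design), Gaussian age (clipped to 18–90),
Bernoulli sex, and status ~ Bernoulli(expit(β0 + β1A + β2B + β3AB +
β_age·age + β_sex·sex)). Defaults are the study conditions: n = 3525,
MAF 0.05 (risk = minor) and 0.48 (risk = major), OR1 = 1.9, OR2 = 1.2,
OR_int = 1.6, β_age = −0.03/yr and β_sex = 1.2 (cases younger, more often
female, matching the reported demographic contrast), β0 = −0.66 chosen from
the closed-form mean linear predictor to give ≈ 37% cases (1318/3525). The
generative interaction coding defaults to the analysis default
(dominant × additive) so recovery tests are well-specified. Randomness is
split into named substreams (genotypes, covariates, outcomes) spawned from
the master seed, so adding covariates never shifts genotype draws; identical
seed + config is bit-identical. An optional subsample fixes case/control
totals for strict case-control sampling.

The expression generator adds a per-allele effect, group offsets (four
ethnicity-like groups by default) and Gaussian noise. The qPCR generator
encodes condition folds in the true ΔCt (reference ΔCt 8.0 over a
housekeeping baseline of Ct 18), with fold 1 for all conditions at t = 0
(pre-stimulation), per-measurement Gaussian Ct noise (sd 0.15, a typical
technical-replicate spread) on both channels, and 3 biological × 3 technical
replicates per cell. Injected synergy multiplies the combined condition's
fold at chosen (gene, timepoint) cells.

What the generators deliberately do not emulate: linkage disequilibrium,
population stratification, genotyping error, batch effects in expression,
amplification-efficiency drift or outlier Ct values. Passing recovery and
calibration tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to those real-data complications.

## Simulation study sizes and numerical choices

Monte-Carlo studies default to: type-I error of the Wald interaction test at
n = 2000, 500 replicates, MAFs 0.20/0.48 (the rarer variant lifted from 0.05
so the interaction cell keeps enough carriers for Wald asymptotics at that
n); AP CI coverage at n = 2000, 500 replicates, dominant × dominant,
MAF 0.3/0.3, true AP ≈ 0.316 implied by ORs (1.5, 1.5, 1.5·1.5·1.3), with no
covariates since they are not part of that estimand; parameter recovery and
power at the full study scale (n = 3525, 200 replicates), with recovery
summarized as geometric-mean ORs (means of log-ORs, the scale on which the
estimator is asymptotically unbiased) against truth with Monte-Carlo SEs.
Replicate seeds are spawned deterministically from one master seed. These
sizes keep each study in the tens of seconds on a single CPU while holding
binomial Monte-Carlo error small against the acceptance bands.

## Known limitations

- Published adjusted estimates bundled with the fixtures (ORs 1.9/1.2,
  stratum ORs, OR_int = 1.6, AP = 0.42) cannot be recomputed from counts:
  they required individual-level covariates. Reports therefore always label
  crude vs published-adjusted values; the crude recomputations land close
  (within ~13% on every OR) but not equal.
- Wald inference only; no score/likelihood-ratio tests, no Firth correction,
  no permutation p-values, no >2-way interactions.
- The PLINK reader handles only biallelic .ped/.map files and infers allele
  orientation from frequencies unless risk alleles are supplied.
- OLS eQTL assumes homoscedastic Gaussian residuals; no rank-normalization
  or mixed-model relatedness adjustment.
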