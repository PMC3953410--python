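# Methods

## Score definition and missing-data rule

The genetic risk score is the unweighted sum of BMI-increasing allele
dosages over a SNP subset. Unweighted counting (rather than β-weighted
scoring) is the primary definition; a weighted score is deliberately not
offered as a default because the panel's external effect sizes come from
other ancestries and would import their winner's-curse and transferability
biases into the score itself.

Missing dosages are mean-imputed with the SNP's average allele count
computed on the delivered analysis sample — not from the panel's nominal
effect-allele frequency — because the sample mean is the quantity that
leaves the score total invariant in expectation under missingness completely
at random. A `2·EAF` fallback (`impute_from_eaf=True`) exists for scoring a
handful of individuals where no sample mean is estimable. Individuals
missing more than `max_missing` (default 3) subset genotypes are excluded
and enumerated in the result rather than silently imputed; the cap is a
conservative reading of typical panel completeness in chip-genotyped
cohorts and is configurable.

## Panel fixture and its assumptions

The packaged table carries 28 BMI loci with gene, rsID, effect allele,
other allele and effect-allele frequency, flagged into a 24-SNP
European-ancestry (EA) discovery set and an 11-SNP East-Asian (EAA)
discovery set with 7 loci in both. Frequencies are those of a Chinese Han
cohort. Two columns are explicit assumptions rather than measured facts:

* **Alleles.** The source table identifies loci by rsID and frequency only;
  allele labels were assigned from the discovery-GWAS literature where well
  established (e.g. FTO rs9939609 A/T — a genuine A/T palindrome, kept so
  the strand-ambiguity flag is exercised by real panel content) and
  otherwise as plausible non-palindromic pairs. Dosage semantics are
  unaffected: the effect allele is whichever allele the panel designates.
* **EAA membership.** The four East-Asian-only loci are PCSK1, CDKAL1, KLF9
  and GP2; the seven EA∩EAA loci are taken to be FTO, SEC16B, MC4R, GIPR,
  RBJ, BDNF and MAP2K5 (the loci reported at genome-wide significance in
  East-Asian meta-analyses). With this membership the EA/EAA subset score
  expectations (2·Σf = 20.4 and 7.4) differ somewhat from published
  ancestry-specific score means, which depend on the exact (unpublished)
  membership; the overall 28-SNP score is unaffected.
* The `imputed` column is a placeholder (all false): which panel SNPs were
  chip-typed versus statistically imputed is cohort-specific metadata.
* `ref_beta`/`ref_se` (external effects for heterogeneity testing) ship
  empty; `cochran_q` takes explicit estimates.

## Quality control

Call rate and an exact Hardy–Weinberg test per SNP, with default thresholds
call rate ≥ 0.95 and HWE p ≥ 0.01. The HWE test is the exact conditional
test: given the allele totals, the probability of each attainable
heterozygote count is computed and the two-sided p-value sums all counts
whose probability does not exceed the observed one. Up to n = 2000 the
weights are exact integers (no rounding in the tie comparison); above that
a log-space recurrence with running renormalisation is used, with a 1e-12
relative tie tolerance. Monomorphic SNPs pass the HWE test trivially
(single attainable configuration, p = 1) but fail QC with their own reason
code, since a monomorphic locus contributes nothing to a count score.
QC annotates and reports; it never drops columns itself — downstream stages
take an explicit kept-SNP list.

The two-population genotype-distribution comparison is a G-test (2×3 by
default, 2×2 allele-level behind a flag) with expected counts from pooled
category proportions; categories empty in both populations are dropped with
a df reduction noted in the result.

## Association models

Ordinary least squares with intercept for quantitative traits; Newton IRLS
logistic regression (tolerance 1e-8, ≤50 iterations) for weight-class
contrasts with Wald CIs, matching OR (95% CI) reporting. Separation and
non-convergence raise with a diagnostic rather than returning unstable
estimates. Complete-case filtering is per model, so the analysis n floats
per trait (DXA fat percentages typically exist only for a cohort subset).
Rank-deficient designs are rejected naming the collinear columns. Age² is
always built internally from the age column; sex (male=1) and region
(Shanghai=1) are 0/1 indicators with the reference level recorded in the
result metadata.

The inverse-normal transform maps ranks through Φ⁻¹((r − c)/(n − 2c + 1))
with the Blom offset c = 3/8 (configurable) and average ranks for ties;
missing values pass through. Rank-based INT makes per-allele effects
comparable across traits with different units and skew.

Explained variance of a biallelic locus uses 2f(1−f)β² with β the
per-allele effect on the standardized trait; the formula is symmetric in
f ↔ 1−f, so the implementation folds f to min(f, 1−f) and effect-allele
frequencies above 0.5 need no special-casing.

## Interaction and consistency statistics

The PA interaction is one joint OLS with score, ordinal PA (0/1/2) and
their product, plus covariates. PA enters the joint model ordinally because
the interaction is summarised as a per-category-step change; stratum
effects are separate per-stratum fits (this is what per-stratum standard
errors imply), with covariates constant within a stratum absorbed into the
intercept. The joint model's score coefficient is the per-allele effect in
the PA-reference (low) category.

Sign tests of directional consistency are exact one-sided upper binomial
tails at p = 1/2, computed in integer arithmetic; one-sided because the
alternative (discovery directions replicate more often than chance) is
directional. Betas of exactly zero count as inconsistent and are tallied
separately. Cochran's Q for two studies uses fixed-effect inverse-variance
weights on 1 df; I² = max(0, (Q−1)/Q) is attached as a supplementary
descriptive.

## Synthetic cohorts

The generator is the analysis model run forward. Genotypes are independent
Binomial(2, f) draws — Hardy–Weinberg by construction at the panel
frequencies; linkage disequilibrium between loci is deliberately absent,
so tests exercise the independent-loci regime the count score assumes and
say nothing about correlated panels. Covariates: age uniform on 50–70
years, sex and region Bernoulli(1/2), two standard-normal PCs; the PA
category defaults to the (219, 1226, 1449)/2894 low/moderate/high mix of a
middle-aged cohort assessed with the short IPAQ questionnaire. BMI is

trait_mean + Σ β<sub>j</sub> g<sub>j</sub> + covariate effects
+ δ·(GRS − 2Σf)·PA + ε,  ε ~ N(0, σ²)

with genetic effects parameterized either per SNP or through the summed
score (exactly one active). The interaction acts on the *centered* score
(centered at the analytic expectation 2·Σf, not the sample mean, to keep
generation deterministic in distribution across n): this keeps stratum
main effects interpretable and makes the uncentered analysis model's score
coefficient equal the generating per-allele effect. Fat-percentage traits
are generated analogously with their own means, per-allele effects and
residual SDs.

Free parameters the analysis model does not pin down were fixed once:
residual BMI SD σ = 3.6 kg/m², calibrated so that a per-allele effect of
0.11 kg/m² on the 28-SNP score explains ≈0.9% of BMI variance
(2Σf(1−f)·β²/σ²_total); trait mean 23.5 kg/m²; small covariate effects
(0.02 kg/m² per year of age, −0.3 for male sex, 0.2 for region, 0.1 per
PC) that give the adjustment sets something real to absorb without
dominating the variance. Fat-trait defaults (means 30/15/10%, per-allele
effects 0.14/0.10/0.03%, residual SDs 6/4/2%) are in the range reported
for DXA-measured middle-aged East-Asian cohorts.

Genotype missingness is applied only to the emitted matrix, never to the
trait equation, so imputation-rule tests have an exact truth. A single
`numpy` Generator seeded from the config drives all draws in a fixed
order: identical configs give identical cohorts.

`simulated_power` estimates power by direct simulation (≥100 replicates per
grid point, Clopper–Pearson 95% CI on the rejection fraction) for either
the score main effect or the interaction.

## Numerical and reporting choices

* Exact-test tie comparisons are exact-integer at QC-relevant sample sizes;
  the recurrence branch is reserved for very large n.
* p-values render with two significant figures, switching to scientific
  notation below 0.001 (`1.54E-07` style); effects and ORs render to two
  decimals with SE/CI in parentheses.
* The Bonferroni threshold is plain α/m with m supplied by the caller — the
  effective test count is a study-design decision, never hard-coded.
* Pipeline determinism: one root seed in the config, a config content hash
  and per-stage row counts (with named exclusions) in the run manifest;
  re-running a manifest's config reproduces every output byte.

## Problem sizes used in the test suite

Chosen as the package's own validation design: score-distribution checks
at n = 100,000 (Monte-Carlo SE on the mean ≈ 0.01 alleles); parameter
recovery at n = 2894 over 200 seeds; null calibration of main-effect and
interaction type-I error over 4000 cohorts of n = 300 on a 6-SNP subpanel
(the t-test's calibration does not depend on panel width, and the larger
replicate count tightens the Monte-Carlo band); exhaustive
oracle-equivalence enumeration for all genotype tables up to n = 40 plus a
seeded sample of tables up to n = 200.

## Known limitations

* No LD, genotyping error, imputation uncertainty or population structure
  beyond two synthetic PCs; passing tests validate the statistics, not
  robustness to those artefacts.
* The exact HWE recurrence above n = 2000 carries double-precision tie
  resolution (1e-12 relative), adequate for QC but not for exact-rational
  reproducibility at that scale.
* Logistic inference is Wald-based; with very sparse cases
  (e.g. per-SNP obesity contrasts in small strata) profile-likelihood CIs
  would be preferable and are not implemented.
* The multiplicative (logistic) scale interaction is not implemented; the
  effect-modification model is linear-scale only.
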