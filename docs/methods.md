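# Methods

This note records the statistical models implemented in `haplorisk`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Data model

Genotypes are unordered allele pairs at biallelic SNPs, stored as
minor-allele counts (0/1/2; −1 missing) against a locus registry that
fixes, per SNP, the gene, the major/minor allele labels and the position
of the SNP's allele in the gene's haplotype string. The packaged registry
covers the 20-SNP five-gene panel (CRP: rs2794521, rs1800947, rs1130864;
COL1A1: rs1107946, rs1800012; IL6: rs1800795, rs1800796, rs1800797,
rs2069827, rs12700386, rs10499563; VDR: rs2228570, rs1544410, rs731236;
eNOS: rs2070744, rs1799983, rs1800780, rs3918181, rs891512, rs1808593).
Two frequently mistyped rsIDs (rs18008593, rs391881) are aliased to
rs1808593 and rs3918181 with a warning.

Missing genotypes ("./." or "NA") are handled per locus for MAF/HWE
(statistics use observed calls) and per gene for phasing (a sample
missing any SNP of a gene is excluded from that gene's EM, logged).
Covariate dichotomization uses single thresholds (SBP > 120, DBP > 80,
TC > 200, LDL > 100, TG > 150 mg/dL; PSQI sleep score ≥ 5; IL-6, IL-1β,
TNF-α > 3 pg/mL; hsCRP > 3 mg/L). BMI was described in the source tables
as a "<25 vs ≥30 kg/m²" contrast, which leaves 25–30 undefined; because
regression and scoring need a total dichotomy, the default rule scores
BMI ≥ 30 as 1 and everything below as 0. The rule objects are
configurable if an analyst prefers to drop the midband.

## Haplotype EM

Per gene, EM runs over the haplotype space restricted to haplotypes
compatible with at least one observed genotype. E-step weights each
compatible unordered pair by its Hardy–Weinberg probability under current
frequencies; M-step re-estimates frequencies from expected haplotype
counts. Convergence: max |Δf| < 1e-8 or log-likelihood change < 1e-8,
capped at 1000 iterations; the monotonicity of the log-likelihood is
asserted on every iteration. Because multi-locus likelihoods can be
multimodal, the fit is best-of-restarts: one uniform start plus
Dirichlet(1) random starts (default 5 total, seeded). Haplotypes with
fitted frequency < 1e-6 are pruned from the report.

Association operates on subject-level carriage, matching the carrier
counts that candidate-gene studies print: each sample is assigned its
maximum-posterior haplotype pair (ties broken toward the
lexicographically smaller pair so runs are reproducible), and the mean
max-posterior probability is retained as a phase-certainty summary.
Haplotypes below a 5% carrier fraction in *both* groups are excluded
from association (a count-based variant of the rule is available).
"Coverage" of a retained haplotype set is its summed estimated
frequency — the operational reading of "genetic variance captured" that
is consistent with published 85–95% figures.

At the study's sample size the binding error in recovering a generating
frequency vector is multinomial sampling of 2n chromosomes, not phase
inference: at n = 287 with a six-haplotype vector whose largest frequency
is 0.62, even an estimator that observes true phase has only ≈84%
probability of keeping the maximum absolute frequency error within 0.03,
while the EM estimate stays within 0.03 of the *realized* sample
frequencies in essentially every replicate (asserted in the test suite).

## Association and inheritance modes

Unadjusted haplotype effects are carrier-vs-referent-carrier 2×2 odds
ratios with Woolf intervals and Pearson chi-square p-values; a subject
carrying both the haplotype and the referent contributes to both margins
(this is the arithmetic that reproduces published carrier tables). Zero
cells receive the Haldane–Anscombe +0.5 on all four cells, flagged.
Adjusted effects refit a logistic model of status on the carriage
indicator plus the six dichotomized risk indicators, restricted to
carriers of the haplotype or the referent; indicators constant within
that subset are dropped (logged). Bonferroni correction multiplies each
p by the number of haplotypes tested within the gene.

Logistic fits use maximum likelihood (IRLS) with observed-information
standard errors. Quasi-complete separation — a real risk in sparse
haplotype × covariate cells — is detected (diverging coefficients) and
either raised as an error or, in pipeline contexts, replaced by a
Firth-penalized (Jeffreys-prior) fit, always flagged in the output.
AIC is 2k − 2 ln L with k the number of estimated parameters.

Inheritance modes encode copy number c as: dominant 1{c≥1}, recessive
1{c=2}, multiplicative c (so the multiplicative column is exactly the sum
of the other two), and general as two indicators 1{c=1}, 1{c=2} against
the zero-copy referent. Modes whose encoding is constant in the sample
(e.g. recessive with no homozygotes) are skipped with a warning. The best
mode minimises AIC; the report cross-checks agreement with the maximum of
R²h and notes discrepancies rather than hiding them.

R²h — the "haplotype uncertainty" fit measure — is defined here as the
Nagelkerke pseudo-R² of the haplotype model multiplied by the mean
posterior certainty of the carriage calls used; both factors are reported
separately. This is an explicit operationalization: the measure's
original software definition is unpublished, so no numerical agreement
with published R²h values is claimed, only the intended behaviour
(perfect prediction with unambiguous phase → 1; attenuation exactly
proportional to phase uncertainty).

## Epistasis scan

For each SNP pair and quantitative trait (the PSQI sleep score enters as
its raw integer score, since component F-tests need a quantitative
response), the trait is regressed on [1, a₁, a₂, d₁, d₂, a₁a₂, a₁d₂,
d₁a₂, d₁d₂]. Component tests are single-coefficient F-tests; the overall
interaction test is the joint F-test of the four products. Genotype
classes with fewer than `min_cell = 5` members collapse into the
neighbouring class on the additive axis (flagged); columns aliased by
missing joint genotype classes — which strong within-gene LD produces
structurally — are dropped greedily and their components reported as
untestable rather than zero. Bonferroni uses the number of (pair × trait)
tests actually performed, recorded in the scan metadata. The regression
a/d coding is a standard equivalent of sum-to-zero two-locus contrast
weighting; validation is by planted-signal recovery and null calibration
of the 4-df test, not by comparison to any specific published scan. A
pair's label (AA/AD/DA/DD) is the significant component with the smallest
corrected p; "I" when only the joint test rejects. Significant pairs
export as a GraphML multigraph (one edge per significant pair × trait).

## Risk scores and ROC

κ-standardization: κ = 1/min|β| over the model's components, integer
weight = β·κ rounded half away from zero (round-half-even would flip
weights at exact .5 ties), so weights are invariant to any positive
rescaling of β. Haplotype GRS: per member SNP of a susceptibility
haplotype, the risky allele is the allele that haplotype carries; each
SNP contributes 0/1/2 copies and the score is the sum. A missing member
genotype contributes 0 and is counted; samples missing more than one
member SNP are excluded from ROC (logged).

AUC is the tie-corrected Mann–Whitney concordance; its SE follows Hanley
& McNeil, with a Wald 95% interval truncated to [0, 1]. Model ladders
refit a logistic model per specification and score subjects by predicted
probability — the self-consistent way to put binary clinical indicators
and integer genetic scores on one scale; a κ-weighted-sum scoring variant
(z-scoring non-binary components) is available. Paired AUC differences
use DeLong's covariance test.

## Power and population structure

Power is Monte-Carlo: control genotype counts drawn from Hardy–Weinberg
proportions at the stated MAF, case counts from the genotype distribution
reweighted by (1, r, r²), (1, r, r) or (1, 1, r) for multiplicative,
dominant, recessive genotype relative risk r; the default test is the
genotypic 2×3 Pearson chi-square (degrees of freedom reduced when a
genotype column is empty), with an allelic 2×2 option. MDRR inverts the
power curve by bisection with common random numbers. The exact HWE test
conditions on observed allele counts and sums the probabilities of
heterozygote counts no more probable than the observed one. The
stratification check is the two-group Weir–Cockerham θ per locus with the
ratio-of-sums multi-locus mean and a delete-one-locus jackknife SE; loci
with identical group frequencies contribute exactly zero by convention
(the raw estimator's small-sample bias term would otherwise report
spurious negative differentiation for identical groups).

## Synthetic cohorts

The generator draws, per subject: two haplotypes per gene independently
from gene-level frequency vectors (Hardy–Weinberg pairing, linkage
equilibrium between genes — the five genes lie in distinct genomic
regions); clinical covariates from control-like marginals (normal for
BMI/SBP/DBP/TC/TG/LDL, log-normal matched to median and quartiles for the
cytokines, Poisson(3.3) clipped to 0–21 for the PSQI score, giving
P(score ≥ 5) ≈ 0.24, Bernoulli for smoking/alcohol); then disease status
from a logistic model over encoded haplotype copies and dichotomized
covariate indicators (default intercept −3.5, population prevalence
≈ 0.2), sampling until the case and control quotas fill (case-control
ascertainment). Same seed, same cohort, bit for bit.

Default haplotype frequencies derive from published control-group carrier
fractions by solving 1 − (1 − p)² = carrier fraction and renormalizing
per gene — an approximation, since the printed tables cover only common
haplotypes. Two consequences are worth knowing. First, the published
IL-6 haplotype labels are not all representable on a biallelic alphabet
(three distinct characters appear at some positions across the printed
strings); the generator keeps the referent GGGGGT, the susceptibility
haplotype GGGGCT and CGAGGC verbatim and remaps the other labels
minimally onto valid, distinct strings. Second, the carrier-fraction and
per-SNP MAF summaries of the source cohort are mutually inconsistent
under HWE and linkage equilibrium (a referent carried by only 25% of
subjects cannot coexist with uniformly low minor-allele frequencies), so
the per-SNP MAFs implied by the defaults — exposed by
`implied_maf_table()` — deviate from the published per-SNP values, in
places substantially, and the registry's "minor" allele can exceed 0.5
(a polarity warning is logged). The generator is parameterized at the
haplotype level because haplotype structure is what the downstream
stages consume.

What the generator does **not** emulate: covariate correlations (marginals
are independent by default; a correlation matrix can be supplied),
measurement error beyond the stated noise models, within-gene
recombination, genotyping error or missingness patterns, and the
radiographic grading process. Passing recovery tests on these cohorts
therefore demonstrates correctness of the estimators under the stated
generative assumptions, not robustness to the messiness of real cohorts.

A note on effect direction: a recessive haplotype effect enriches
homozygotes, not carriers — heterozygous carriers dilute the carrier
odds ratio toward 1. Direction checks on simulated cohorts therefore
test homozygote-fraction enrichment and the sign of the mean carrier
log-OR across replicates rather than demanding a large carrier OR in
every replicate.

## Problem sizes used in the test and acceptance suites

EM recovery: 200 replicates at n = 287 (six-haplotype gene).
Inheritance-mode recovery: 100 cohorts of 279/287 with a recessive
β = 2.11 planted. Epistasis: 200 planted-DD replicates and 1000 null
replicates at n = 280. ROC ordering: 100 default cohorts. Power:
5000–20000 Monte-Carlo replicates. These sizes give stable rates while
keeping the default suite fast on a single core.

## Known limitations

- Phasing is per-gene enumeration EM; blocks much longer than ~10 SNPs
  would need partition–ligation or sampling, which is out of scope.
- The general (2-df) inheritance mode needs all three copy-number classes;
  rare haplotypes often cannot support it and it is skipped.
- Apparent (resubstitution) AUC only — no cross-validation or external
  validation; ladders inherit the optimism of refitted models.
- The Fst module is two-group only, by design (case/control
  stratification check, not a population survey).
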