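# haplorisk

Case-control genetics of multifactorial disease, end to end: haplotype
inference from unphased SNP genotypes, carrier-based association with
inheritance-mode selection, two-locus epistasis decomposition, weighted
genetic/clinical risk scores and ROC model comparison. The package was
built around a knee-osteoarthritis candidate-gene study design — 20 SNPs
in five inflammatory genes (CRP, COL1A1, IL6, VDR, eNOS), pro-inflammatory
biomarkers (IL-6, IL-1β, TNF-α, hsCRP) and clinical risk variables — but
every stage is generic for biallelic SNP panels grouped into genes.

It is written for biostatisticians and genetic epidemiologists who need a
reproducible, scriptable version of the classic candidate-gene workflow:
per-locus QC (gene-counting MAF, exact Hardy–Weinberg test, Weir–Cockerham
F_ST stratification check, Monte-Carlo power/MDRR), per-gene haplotype
analysis, and predictive-model building.

## The models at the core

**Haplotype EM.** Within a gene of L SNPs, unphased genotypes are
compatible with up to 2^(h−1) haplotype pairs (h heterozygous sites). With
haplotype frequencies f and Hardy–Weinberg pairing, the E-step weights each
compatible pair (h_i, h_j) by 2^{[i≠j]} f_i f_j and the M-step re-estimates
f from expected counts — the Excoffier–Slatkin gene-counting EM. The fitted
object carries per-sample posteriors over pairs; association uses
max-posterior carriage (copies of each haplotype per subject).

**Association.** Each haplotype is compared with the gene's most prevalent
haplotype (the referent) on a carriers-versus-referent-carriers 2×2 table:
OR = ad/bc with the Woolf interval exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)).
Covariate-adjusted estimates come from logistic regression of status on
the carriage indicator plus dichotomized risk indicators (BMI, TG, poor
sleep, IL-6, IL-1β, hsCRP), with Bonferroni correction per gene. Haplotype
copy number is then encoded under dominant / recessive / multiplicative /
general (2-df) inheritance modes; the best-fitting mode minimises
AIC = 2k − 2 ln L, cross-checked against R²h, a Nagelkerke pseudo-R²
attenuated by the mean posterior phase certainty.

**Epistasis.** For a SNP pair and a quantitative trait, additive codes
a ∈ {−1, 0, +1} and dominance codes d ∈ {−½, +½, −½} define four product
terms whose single-df F-tests partition interaction into AA, AD, DA and DD
components; the joint 4-df F-test is the overall "interactive" test.

**Risk scores and ROC.** Logistic coefficients are κ-standardized
(κ = 1/min|β|, weights = round(β·κ)) into integer weights over binary risk
indicators; susceptibility-haplotype genetic risk scores count risky-allele
copies 0/1/2 per member SNP. Candidate models are compared by AUROC
(Mann–Whitney concordance, Hanley–McNeil SE, DeLong test for paired
differences).

Because the motivating study's individual-level data are not deposited,
the package ships a seeded synthetic-cohort generator
(`haplorisk.simulate`) whose defaults reproduce the published summary
structure: per-gene haplotype frequencies from the control carrier table,
covariate marginals from the baseline table, and the four
susceptibility-haplotype effects in their best-fit modes (AGT recessive
2.11, GGGGCT recessive 2.75, AGC dominant 2.35, CTAAAT multiplicative
1.89) with the multivariable covariate coefficients.

## Worked example

```python
import haplorisk as hr

geno, pheno, truth = hr.simulate_cohort(hr.CohortSpec(seed=1))

sol  = hr.HaplotypeEM(geno, "VDR").fit(seed=1)
carr = hr.posterior_carriage(sol)
masks = {"case": pheno.case_mask, "control": pheno.control_mask}
carr = hr.filter_rare_haplotypes(carr, 0.05, masks)

print(hr.HaplotypeAssociation(carr, pheno).fit().summary().round(3))

scan = hr.InheritanceModeScan(carr.copy_counts("AGC"), pheno,
                              certainty=carr.certainty).fit()
print(scan.summary().round(3), "best:", scan.best_mode)
```

prints (seed 1):

```
gene haplotype referent  case_carriers  control_carriers    OR  OR_low  OR_high     p  adj_OR  ...
 VDR       AGC      GGT             60                11 5.639   2.893   10.988 0.000   9.371  ...
 VDR       GTT      GGT             39                66 0.611   0.396    0.943 0.025   0.576  ...
 VDR       ATT      GGT             34                44 0.799   0.493    1.293 0.360   0.781  ...
 VDR       ATC      GGT             64                53 1.248   0.832    1.872 0.283   1.363  ...
 VDR       GTC      GGT             16                32 0.517   0.276    0.967 0.036   0.471  ...

haplotype           mode  beta    se  wald   p   r2h     aic  best
      AGC       dominant 2.296 0.372 6.179 0.0 0.306 649.381  True
      AGC multiplicative 2.296 0.372 6.179 0.0 0.306 649.381 False
best: dominant
```

The generator planted a dominant AGC effect of β = 2.35; the association
stage finds AGC strongly enriched in cases (carrier OR 5.6), and the mode
scan recovers β̂ = 2.30 (SE 0.37) with the dominant encoding selected by
AIC. (This replicate drew no AGC homozygotes, so the recessive and general
encodings are skipped with a warning and the dominant and multiplicative
columns coincide.)

The same analyses are scriptable from the shell:

```sh
haplorisk simulate --seed 1 --out-prefix sim/
haplorisk assoc --geno sim/genotypes.csv --pheno sim/phenotypes.csv \
    --gene VDR --out vdr_assoc.tsv
haplorisk run --config run.yml          # full pipeline + manifest
```

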