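"""Seeded synthetic case-control cohorts.

The generator emulates the statistical structure the analysis assumes: per
gene, two haplotypes per subject drawn independently from a gene-level
frequency vector (Hardy-Weinberg pairing, linkage equilibrium between
genes); clinical covariates drawn from control-like marginal
distributions; disease status from a logistic model over encoded
haplotype copy numbers and dichotomized covariate indicators, with
case-control ascertainment (sampling continues until both quotas fill).

Default parameters mirror the observed cohort: per-gene control carrier
fractions converted to chromosome frequencies via 1-(1-p)^2 = carrier
fraction and renormalized, covariate means/SDs (log-normal
median/quartile matches for the cytokines), the multivariable covariate
coefficients, and the four susceptibility-haplotype effects in their
best-fit inheritance modes (AGT recessive 2.11, GGGGCT recessive 2.75,
AGC dominant 2.35, CTAAAT multiplicative 1.89).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (DichotomizationRules, GenotypeDataset, PhenotypeTable,
                   PHENOTYPE_COLUMNS)
from .registry import LocusRegistry, default_registry

#: Control-group carrier fractions per haplotype (subject-level).
CONTROL_CARRIER_FRACTIONS = {
    "CRP": [("AGC", 0.54), ("GGT", 0.07), ("AGT", 0.09), ("GCT", 0.07),
            ("GCC", 0.08)],
    "COL1A1": [("GG", 0.57), ("GT", 0.13), ("TG", 0.10), ("TT", 0.08)],
    # Haplotype strings spelled on the registry's biallelic alphabet;
    # the referent and the susceptibility haplotype keep their published
    # labels, minor variants were remapped to valid allele pairs.
    "IL6": [("GGGGGT", 0.25), ("CCGTGC", 0.07), ("CCAGCT", 0.07),
            ("GGGGCT", 0.07), ("CCGTCT", 0.08), ("CCGTCC", 0.07),
            ("CCATCT", 0.09), ("CGAGGC", 0.14)],
    "VDR": [("GGT", 0.51), ("ATC", 0.09), ("GTT", 0.09), ("AGC", 0.06),
            ("ATT", 0.07), ("GTC", 0.05)],
    "ENOS": [("TTAGGG", 0.19), ("TTGGGG", 0.14), ("CGAAGG", 0.13),
             ("CTAAAT", 0.08), ("CGGAGG", 0.09), ("CTGGAT", 0.09),
             ("TTAGAT", 0.06)],
}

#: Susceptibility-haplotype effects (gene, haplotype, mode, beta).
DEFAULT_HAPLOTYPE_EFFECTS = [
    ("CRP", "AGT", "recessive", 2.11),
    ("IL6", "GGGGCT", "recessive", 2.75),
    ("VDR", "AGC", "dominant", 2.35),
    ("ENOS", "CTAAAT", "multiplicative", 1.89),
]

#: Multivariable covariate coefficients on the dichotomized indicators.
DEFAULT_COVARIATE_BETAS = {
    "BMI": 0.667, "LDL": 0.451, "TG": 0.891, "sleep": 1.153,
    "IL6": 1.098, "IL1B": 0.920, "HSCRP": 0.501,
}

#: Control-group marginals: normal (mean, sd) for clinical measures.
NORMAL_COVARIATES = {
    "BMI": (26.72, 4.45), "SBP": (133.05, 22.22), "DBP": (84.91, 14.42),
    "TC": (163.29, 39.40), "TG": (155.72, 28.60), "LDL": (152.34, 27.39),
}

#: Log-normal (median, q1, q3) for the cytokine panel.
LOGNORMAL_COVARIATES = {
    "IL6": (2.3, 0.9, 3.4), "IL1B": (1.5, 0.7, 2.4),
    "TNFA": (1.4, 0.6, 2.2), "HSCRP": (1.3, 0.7, 1.9),
}

BINARY_COVARIATES = {"smoker": 0.286, "alcohol": 0.307}

#: Poisson rate for the PSQI global sleep score; gives P(score >= 5)
#: of about 0.24, the control-group poor-sleep fraction.
SLEEP_POISSON_RATE = 3.3


def carrier_to_chromosome_freqs(pairs) -> list[tuple[str, float]]:
    """Chromosome frequencies from subject-level carrier fractions.

    Solves 1 - (1 - p)^2 = carrier fraction per haplotype under HW
    pairing, then renormalizes the gene's vector onto the simplex (the
    published carrier table covers only the common haplotypes).
    """
    raw = [(h, 1.0 - math.sqrt(1.0 - c)) for h, c in pairs]
    tot = sum(p for _, p in raw)
    return [(h, p / tot) for h, p in raw]


def default_hap_freqs() -> dict:
    return {g: carrier_to_chromosome_freqs(v)
            for g, v in CONTROL_CARRIER_FRACTIONS.items()}


@dataclass
class CohortSpec:
    """Generative parameters for a synthetic case-control cohort."""

    n_cases: int = 279
    n_controls: int = 287
    hap_freqs: dict = field(default_factory=default_hap_freqs)
    hap_effects: list = field(
        default_factory=lambda: list(DEFAULT_HAPLOTYPE_EFFECTS))
    covariate_betas: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_BETAS))
    intercept: float = -3.5
    seed: int = 0
    max_draw_factor: int = 200

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        for gene, pairs in self.hap_freqs.items():
            tot = sum(p for _, p in pairs)
            if abs(tot - 1.0) > 1e-8:
                raise ValueError(
                    f"gene {gene}: haplotype frequencies sum to {tot}")


def _encode(copies: np.ndarray, mode: str) -> np.ndarray:
    if mode == "dominant":
        return (copies >= 1).astype(float)
    if mode == "recessive":
        return (copies == 2).astype(float)
    if mode == "multiplicative":
        return copies.astype(float)
    raise ValueError(f"unknown mode {mode!r}")


def _lognormal_params(median, q1, q3):
    mu = math.log(median)
    sigma = math.log(q3 / q1) / (2 * 0.6744897501960817)
    return mu, sigma


def _draw_covariates(rng, m: int) -> pd.DataFrame:
    cols = {}
    for name, (mean, sd) in NORMAL_COVARIATES.items():
        cols[name] = np.maximum(rng.normal(mean, sd, m), 0.0)
    cols["sleep"] = np.minimum(rng.poisson(SLEEP_POISSON_RATE, m), 21)
    for name, p in BINARY_COVARIATES.items():
        cols[name] = rng.binomial(1, p, m)
    for name, (med, q1, q3) in LOGNORMAL_COVARIATES.items():
        mu, sigma = _lognormal_params(med, q1, q3)
        cols[name] = rng.lognormal(mu, sigma, m)
    return pd.DataFrame(cols)


def _hap_minor_vector(hap: str, loci) -> np.ndarray:
    out = np.empty(len(hap), dtype=np.int8)
    for i, (allele, locus) in enumerate(zip(hap, loci)):
        if allele == locus.allele_minor:
            out[i] = 1
        elif allele == locus.allele_major:
            out[i] = 0
        else:
            raise ValueError(
                f"{locus.snp_id}: allele {allele!r} not registered")
    return out


def simulate_cohort(spec: CohortSpec,
                    registry: LocusRegistry | None = None,
                    rules: DichotomizationRules | None = None):
    """Draw a cohort to quota; returns (genotypes, phenotypes, truth).

    The truth record carries the drawn haplotype pairs per gene, the
    generating parameters, and the achieved population prevalence.
    """
    registry = registry or default_registry()
    rules = rules or DichotomizationRules()
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.hap_freqs)
    gene_loci = {g: registry.gene_loci(g) for g in genes}
    hap_bits = {
        g: np.vstack([_hap_minor_vector(h, gene_loci[g])
                      for h, _ in spec.hap_freqs[g]])
        for g in genes
    }
    hap_names = {g: [h for h, _ in spec.hap_freqs[g]] for g in genes}
    hap_p = {g: np.array([p for _, p in spec.hap_freqs[g]])
             for g in genes}

    target = spec.n_cases + spec.n_controls
    kept_codes, kept_cov, kept_status, kept_truth = [], [], [], []
    n_cases = n_controls = 0
    n_drawn = 0
    cap = spec.max_draw_factor * target
    batch = max(512, 2 * target)
    while (n_cases < spec.n_cases or n_controls < spec.n_controls):
        if n_drawn >= cap:
            raise RuntimeError(
                f"quota unfilled after {n_drawn} draws (achieved "
                f"prevalence {n_cases / max(n_drawn, 1):.4f}); "
                "check the intercept"
            )
        m = min(batch, cap - n_drawn)
        n_drawn += m
        pair_idx = {g: rng.choice(len(hap_p[g]), size=(m, 2), p=hap_p[g])
                    for g in genes}
        codes = np.concatenate(
            [hap_bits[g][pair_idx[g][:, 0]] + hap_bits[g][pair_idx[g][:, 1]]
             for g in genes], axis=1)
        cov = _draw_covariates(rng, m)
        eta = np.full(m, spec.intercept)
        for name, beta in spec.covariate_betas.items():
            eta += beta * rules[name].apply(cov[name]).to_numpy()
        for gene, hap, mode, beta in spec.hap_effects:
            k = hap_names[gene].index(hap)
            copies = (pair_idx[gene] == k).sum(axis=1)
            eta += beta * _encode(copies, mode)
        prob = 1.0 / (1.0 + np.exp(-eta))
        status = rng.binomial(1, prob)
        for i in range(m):
            if status[i] == 1 and n_cases < spec.n_cases:
                n_cases += 1
            elif status[i] == 0 and n_controls < spec.n_controls:
                n_controls += 1
            else:
                continue
            kept_codes.append(codes[i])
            kept_cov.append(cov.iloc[i])
            kept_status.append(int(status[i]))
            kept_truth.append({
                g: (hap_names[g][pair_idx[g][i, 0]],
                    hap_names[g][pair_idx[g][i, 1]]) for g in genes})

    sample_ids = [f"S{i + 1:05d}" for i in range(target)]
    order = [l.snp_id for g in genes for l in gene_loci[g]]
    reg_order = registry.snp_ids()
    codes = np.vstack(kept_codes)
    codes = codes[:, [order.index(s) for s in reg_order]]
    geno = GenotypeDataset(sample_ids, registry, codes.astype(np.int8))
    pframe = pd.DataFrame(kept_cov).reset_index(drop=True)
    pframe.insert(0, "status", kept_status)
    pframe.insert(0, "sample_id", sample_ids)
    pheno = PhenotypeTable(pframe[[c for c in PHENOTYPE_COLUMNS
                                   if c in pframe.columns]])
    truth = {
        "haplotype_pairs": dict(zip(sample_ids, kept_truth)),
        "hap_freqs": {g: dict(spec.hap_freqs[g]) for g in genes},
        "hap_effects": list(spec.hap_effects),
        "covariate_betas": dict(spec.covariate_betas),
        "intercept": spec.intercept,
        "seed": spec.seed,
        "n_drawn": n_drawn,
        "achieved_prevalence": (np.sum(kept_status) + 0.0) / n_drawn
        if n_drawn else float("nan"),
    }
    return geno, pheno, truth


def simulate_trait_with_epistasis(geno: GenotypeDataset, pair,
                                  component: str = "DD",
                                  effect: float = 1.0,
                                  noise_sd: float = 1.0,
                                  seed: int = 0):
    """Quantitative trait with one planted two-locus interaction term.

    Returns (trait vector, truth dict). ``component`` picks which product
    of additive (a in {-1,0,1}) and dominance (d in {-1/2,1/2,-1/2})
    codes carries the ``effect``; Gaussian noise is added on top.
    """
    snp1, snp2 = pair
    rng = np.random.default_rng(seed)
    c1 = geno.column(snp1).astype(float)
    c2 = geno.column(snp2).astype(float)
    if np.all(c1 == c1[0]) or np.all(c2 == c2[0]):
        raise ValueError("both SNPs of the pair must be polymorphic")
    a1, d1 = c1 - 1.0, np.where(c1 == 1, 0.5, -0.5)
    a2, d2 = c2 - 1.0, np.where(c2 == 1, 0.5, -0.5)
    terms = {"AA": a1 * a2, "AD": a1 * d2, "DA": d1 * a2, "DD": d1 * d2}
    if component not in terms:
        raise ValueError(f"unknown component {component!r}")
    signal = effect * terms[component]
    trait = signal + rng.normal(0.0, noise_sd, len(signal))
    truth = {"pair": (snp1, snp2), "component": component,
             "effect": effect, "noise_sd": noise_sd, "seed": seed,
             "signal_variance": float(np.var(signal))}
    return trait, truth


def implied_maf_table(hap_freqs: dict | None = None,
                      registry: LocusRegistry | None = None
                      ) -> pd.DataFrame:
    """Per-SNP minor-allele frequencies implied by the haplotype defaults.

    A bookkeeping diagnostic: the generator is parameterized at the
    haplotype level, so per-SNP MAFs are derived quantities.
    """
    registry = registry or default_registry()
    hap_freqs = hap_freqs or default_hap_freqs()
    rows = []
    for gene, pairs in hap_freqs.items():
        loci = registry.gene_loci(gene)
        bits = np.vstack([_hap_minor_vector(h, loci) for h, _ in pairs])
        p = np.array([f for _, f in pairs])
        mafs = bits.T @ p
        for locus, maf in zip(loci, mafs):
            rows.append({"gene": gene, "snp_id": locus.snp_id,
                         "implied_maf": float(maf)})
    return pd.DataFrame(rows)
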