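"""Weighted risk scores, haplotype genetic risk scores, and ROC comparison.

Clinical components are scored by kappa-standardization of logistic
coefficients: kappa = 1/min|beta| maps the weakest component to weight 1
and every weight is the rounded product beta*kappa. Haplotype genetic risk
scores count risky-allele copies (0 NN / 1 RN / 2 RR) over the SNPs of a
susceptibility haplotype. Candidate predictive models are compared by the
area under the ROC curve (Mann-Whitney concordance with Hanley-McNeil
standard errors; DeLong's test for paired AUC differences).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import fit_logistic
from .data import GenotypeDataset, PhenotypeTable
from .registry import LocusRegistry

logger = logging.getLogger(__name__)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class RiskScoreModel:
    """kappa-standardized integer weights over binary risk components."""

    components: list[str]
    betas: pd.Series
    kappa: float
    weights: pd.Series

    def score(self, indicators: pd.DataFrame) -> pd.Series:
        """Per-sample weighted total over 0/1 component indicators."""
        missing = [c for c in self.components
                   if c not in indicators.columns]
        if missing:
            raise KeyError(f"indicator columns missing: {missing}")
        mat = indicators[self.components].astype(float)
        return (mat * self.weights).sum(axis=1, skipna=False) \
            .rename("weighted_score")

    def raw_score(self, indicators: pd.DataFrame) -> pd.Series:
        """Unweighted (raw-beta) score, kept for diagnostics."""
        mat = indicators[self.components].astype(float)
        return (mat * self.betas).sum(axis=1, skipna=False) \
            .rename("raw_score")


def build_weighted_scores(betas, components=None) -> RiskScoreModel:
    """Integer weights from fitted coefficients.

    ``betas`` may be a mapping/Series of coefficients or a
    :class:`~haplorisk.association.LogisticFit` (its intercept is
    ignored). kappa = 1/min|beta|, so the smallest-|beta| component gets
    an unrounded weight of exactly 1; all weights are beta*kappa rounded
    half away from zero.
    """
    if hasattr(betas, "params"):
        betas = betas.params.drop("const", errors="ignore")
    betas = pd.Series(betas, dtype=float)
    if components is not None:
        betas = betas[list(components)]
    if (betas == 0.0).any():
        zero = betas.index[betas == 0.0].tolist()
        raise ValueError(f"zero coefficients make kappa undefined: {zero}")
    kappa = 1.0 / float(betas.abs().min())
    weights = pd.Series(_round_half_away(betas.to_numpy() * kappa),
                        index=betas.index)
    return RiskScoreModel(components=betas.index.tolist(), betas=betas,
                          kappa=kappa, weights=weights)


# -- haplotype GRS --------------------------------------------------------

@dataclass
class HaplotypeGRS:
    haplotype: str
    gene: str
    snp_ids: list[str]
    risky_alleles: list[str]
    scores: pd.Series          # per-sample integer total, NaN = excluded
    n_missing: pd.Series

    def summary_by_group(self, masks: dict) -> pd.DataFrame:
        rows = []
        for name, mask in masks.items():
            vals = self.scores[np.asarray(mask, dtype=bool)].dropna()
            rows.append({"group": name, "n": len(vals),
                         "mean": vals.mean(), "sd": vals.std()})
        return pd.DataFrame(rows)


def build_haplotype_grs(geno: GenotypeDataset, haplotype: str, gene: str,
                        registry: LocusRegistry | None = None,
                        max_missing: int = 1) -> HaplotypeGRS:
    """Risky-allele copy score for a susceptibility haplotype.

    The risky allele at each member SNP is the allele the haplotype
    carries there; each SNP contributes 0 (NN), 1 (RN) or 2 (RR) copies
    and the per-sample score is the sum over member SNPs. A missing
    genotype contributes 0 and is counted; samples missing more than
    ``max_missing`` member SNPs get a NaN score (excluded downstream).
    """
    registry = registry or geno.registry
    loci = registry.gene_loci(gene)
    if len(haplotype) != len(loci):
        raise ValueError(
            f"haplotype {haplotype!r} has {len(haplotype)} alleles but "
            f"gene {gene} spans {len(loci)} SNPs"
        )
    total = np.zeros(len(geno), dtype=float)
    missing = np.zeros(len(geno), dtype=int)
    risky = []
    for allele, locus in zip(haplotype, loci):
        if allele not in locus.alleles:
            raise ValueError(
                f"{locus.snp_id}: allele {allele!r} not registered")
        risky.append(allele)
        codes = geno.column(locus.snp_id)
        copies = codes if allele == locus.allele_minor else 2 - codes
        obs = codes >= 0
        total[obs] += copies[obs]
        missing += ~obs
    scores = pd.Series(total, index=pd.Index(geno.sample_ids,
                                             name="sample_id"))
    scores[missing > max_missing] = np.nan
    n_excl = int((missing > max_missing).sum())
    if n_excl:
        logger.info("GRS %s: %d samples excluded (> %d member SNPs "
                    "missing)", haplotype, n_excl, max_missing)
    return HaplotypeGRS(haplotype=haplotype, gene=gene,
                        snp_ids=[l.snp_id for l in loci],
                        risky_alleles=risky, scores=scores,
                        n_missing=pd.Series(missing, index=scores.index))


# -- ROC ------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    thresholds: np.ndarray = field(repr=False, default=None)
    sensitivity: np.ndarray = field(repr=False, default=None)
    one_minus_specificity: np.ndarray = field(repr=False, default=None)

    @property
    def p_vs_chance(self) -> float:
        if self.se == 0:
            return np.nan
        z = (self.auc - 0.5) / self.se
        return float(2 * stats.norm.sf(abs(z)))


def roc_auc(scores, status) -> ROCResult:
    """AUC as the tie-corrected Mann-Whitney concordance probability.

    The standard error follows Hanley & McNeil; the 95% Wald interval is
    truncated to [0, 1]. The returned curve is the monotone step function
    over all observed thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    keep = ~np.isnan(scores)
    scores, status = scores[keep], status[keep]
    n1 = int((status == 1).sum())
    n0 = int((status == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    if np.all(scores == scores[0]):
        logger.warning("constant scores: AUC fixed at 0.5")
        auc = 0.5
    else:
        ranks = stats.rankdata(scores)
        auc = (ranks[status == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
           + (n0 - 1) * (q2 - auc ** 2)) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    thr = np.unique(scores)[::-1]
    sens = np.empty(len(thr) + 2)
    fpr = np.empty(len(thr) + 2)
    sens[0], fpr[0] = 0.0, 0.0
    for i, t in enumerate(thr, start=1):
        pos = scores >= t
        sens[i] = (pos & (status == 1)).sum() / n1
        fpr[i] = (pos & (status == 0)).sum() / n0
    sens[-1], fpr[-1] = 1.0, 1.0
    return ROCResult(
        auc=float(auc), se=se,
        ci_low=max(0.0, auc - 1.96 * se),
        ci_high=min(1.0, auc + 1.96 * se),
        n_cases=n1, n_controls=n0,
        thresholds=thr, sensitivity=sens, one_minus_specificity=fpr)


def _delong_structural(scores, status):
    pos = np.asarray(scores)[status == 1]
    neg = np.asarray(scores)[status == 0]
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > n) + 0.5 * (pos == n)) for n in neg])
    return v10, v01


def delong_test(scores_a, scores_b, status) -> dict:
    """DeLong's paired test for the difference of two correlated AUCs."""
    status = np.asarray(status, dtype=int)
    keep = ~(np.isnan(np.asarray(scores_a, dtype=float))
             | np.isnan(np.asarray(scores_b, dtype=float)))
    status = status[keep]
    sa = np.asarray(scores_a, dtype=float)[keep]
    sb = np.asarray(scores_b, dtype=float)[keep]
    v10a, v01a = _delong_structural(sa, status)
    v10b, v01b = _delong_structural(sb, status)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        return {"diff": float(diff), "z": np.nan, "p": np.nan}
    z = diff / math.sqrt(var)
    return {"diff": float(diff), "z": float(z),
            "p": float(2 * stats.norm.sf(abs(z)))}


# -- model ladder ---------------------------------------------------------

@dataclass
class LadderStep:
    name: str
    components: list[str]
    roc: ROCResult
    scores: pd.Series = field(repr=False, default=None)


@dataclass
class ModelLadderResults:
    steps: list[LadderStep]
    comparisons: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"model": s.name, "components": "+".join(s.components),
             "AUC": s.roc.auc, "SE": s.roc.se,
             "CI_low": s.roc.ci_low, "CI_high": s.roc.ci_high,
             "p_vs_chance": s.roc.p_vs_chance}
            for s in self.steps
        ])


def model_ladder(pheno: PhenotypeTable, features: pd.DataFrame,
                 specifications, method: str = "refit"
                 ) -> ModelLadderResults:
    """AUC ladder over nested score-model specifications.

    ``features`` holds the candidate component columns (dichotomized
    covariate indicators and haplotype GRS columns), aligned with
    ``pheno``. Each specification is ``(name, [component columns])``.

    ``method`` "refit" (default) refits a logistic model of status on the
    named components and scores samples by predicted probability — the
    self-consistent way to place clinical indicators and genetic scores
    on one scale. "weighted" kappa-standardizes the refitted coefficients
    into integer weights and scores by the weighted sum (z-scoring any
    non-binary component first).
    """
    steps = []
    y_all = pheno.frame["status"]
    for name, comps in specifications:
        comps = list(comps)
        if not comps:
            raise ValueError(f"specification {name!r} names no components")
        X = features[comps].astype(float)
        ok = ~X.isna().any(axis=1)
        fit = fit_logistic(y_all[ok].to_numpy(), X[ok], firth="auto")
        if method == "refit":
            design = X[ok].copy()
            design.insert(0, "const", 1.0)
            eta = design.to_numpy() @ fit.params.to_numpy()
            scores = pd.Series(1 / (1 + np.exp(-eta)), index=X.index[ok])
        elif method == "weighted":
            Xz = X[ok].copy()
            for c in comps:
                vals = Xz[c]
                if not vals.isin([0.0, 1.0]).all():
                    Xz[c] = (vals - vals.mean()) / (vals.std() or 1.0)
            model = build_weighted_scores(fit)
            scores = model.score(Xz)
        else:
            raise ValueError(f"unknown method {method!r}")
        roc = roc_auc(scores.to_numpy(), y_all[ok].to_numpy())
        steps.append(LadderStep(name=name, components=comps, roc=roc,
                                scores=scores.reindex(features.index)))
    comps = []
    for i in range(1, len(steps)):
        prev, cur = steps[i - 1], steps[i]
        joint = pd.concat([prev.scores, cur.scores], axis=1,
                          keys=["a", "b"]).dropna()
        test = delong_test(cur.scores.loc[joint.index],
                           prev.scores.loc[joint.index],
                           y_all.loc[joint.index].to_numpy())
        comps.append({"model": cur.name, "baseline": prev.name,
                      "auc_diff": test["diff"], "z": test["z"],
                      "p": test["p"]})
    return ModelLadderResults(steps=steps,
                              comparisons=pd.DataFrame(comps))
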