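"""Locus-level population-genetic statistics.

Minor allele frequencies by gene counting, the exact conditional test of
Hardy-Weinberg equilibrium, Weir-Cockerham Fst between two sample groups
(a population-stratification check), and Monte-Carlo power / minimum
detectable genotype relative risk for the case-control design.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class LocusStats:
    snp_id: str
    group: str
    n_observed: int
    maf: float
    sep: float      # standard error of the proportion
    hwe_p: float


def genotype_counts(codes: np.ndarray) -> tuple[int, int, int]:
    """(hom-major, het, hom-minor) counts over observed calls."""
    obs = codes[codes >= 0]
    return (int((obs == 0).sum()), int((obs == 1).sum()),
            int((obs == 2).sum()))


def maf_by_gene_counting(geno: GenotypeDataset, group_mask=None,
                         group: str = "all") -> list[LocusStats]:
    """Per-locus MAF, SE of the proportion, and exact HWE p-value.

    The frequency is always reported for the registry's minor allele; if
    that allele exceeds 0.5 in this subset a polarity warning is logged.
    """
    if group_mask is None:
        group_mask = np.ones(len(geno), dtype=bool)
    codes = geno.codes[np.asarray(group_mask, dtype=bool)]
    out = []
    for j, locus in enumerate(geno.registry):
        col = codes[:, j]
        n_obs = int((col >= 0).sum())
        if n_obs == 0:
            raise ValueError(f"locus {locus.snp_id}: no observed calls "
                             f"in group {group!r}")
        n0, n1, n2 = genotype_counts(col)
        maf = (n1 + 2 * n2) / (2.0 * n_obs)
        if maf > 0.5:
            logger.warning("locus %s: registry minor allele at frequency "
                           "%.3f > 0.5 in group %s", locus.snp_id, maf,
                           group)
        sep = math.sqrt(maf * (1.0 - maf) / (2.0 * n_obs))
        out.append(LocusStats(locus.snp_id, group, n_obs, maf, sep,
                              hwe_exact((n0, n1, n2))))
    return out


def hwe_exact(counts: tuple[int, int, int]) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and enumerates every
    heterozygote count of matching parity; the p-value is the summed
    probability of tables no more probable than the observed one under
    random pairing of alleles.
    """
    n0, n1, n2 = (int(c) for c in counts)
    if min(n0, n1, n2) < 0 or n0 + n1 + n2 < 1:
        raise ValueError("genotype counts must be nonnegative, total >= 1")
    n = n0 + n1 + n2
    n_minor = n1 + 2 * n2
    n_major = 2 * n - n_minor
    rare = min(n_minor, n_major)
    # log P(het = h | allele counts) up to a shared constant
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.array([
        -math.lgamma(h + 1)
        - math.lgamma((rare - h) // 2 + 1)
        - math.lgamma((n - h - (rare - h) // 2) + 1)
        + h * math.log(2.0)
        for h in hets
    ])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.where(hets == n1)[0][0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# -- Weir-Cockerham Fst ---------------------------------------------------

@dataclass
class FstResult:
    snp_ids: list
    per_locus_fst: np.ndarray
    mean_fst: float
    se: float
    n_loci_used: int


def _wc_components(codes_a: np.ndarray, codes_b: np.ndarray):
    """Weir-Cockerham (1984) variance components a, b, c for one locus."""
    comps = []
    for col in (codes_a, codes_b):
        obs = col[col >= 0]
        n = obs.size
        if n < 2:
            return None
        p = (obs == 1).sum() / (2.0 * n) + (obs == 2).sum() / n
        h = (obs == 1).mean()
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    if pbar <= 0.0 or pbar >= 1.0:
        return None  # monomorphic across both groups
    if p1 == p2:
        # identical group frequencies: no between-group variance by
        # construction; report a zero contribution rather than the
        # estimator's small-sample negative bias term
        return (0.0, 0.0, 0.0)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1.0))
        * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - ((r - 1.0) / r) * s2
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return (a, b, c)


def pairwise_fst(geno: GenotypeDataset, group_a, group_b) -> FstResult:
    """Weir-Cockerham theta per locus plus a ratio-of-sums mean.

    The mean is the standard multi-locus estimator sum(a)/sum(a+b+c); its
    standard error is a delete-one jackknife over loci. Loci monomorphic
    in both groups are excluded and logged.
    """
    mask_a = np.asarray(group_a, dtype=bool)
    mask_b = np.asarray(group_b, dtype=bool)
    snp_ids, per_locus, comp_a, comp_tot = [], [], [], []
    for j, locus in enumerate(geno.registry):
        comp = _wc_components(geno.codes[mask_a, j], geno.codes[mask_b, j])
        if comp is None:
            logger.info("fst: locus %s monomorphic/insufficient; excluded",
                        locus.snp_id)
            continue
        a, b, c = comp
        tot = a + b + c
        snp_ids.append(locus.snp_id)
        per_locus.append(a / tot if tot != 0.0 else 0.0)
        comp_a.append(a)
        comp_tot.append(tot)
    if not snp_ids:
        raise ValueError("no polymorphic loci available for Fst")
    comp_a = np.asarray(comp_a)
    comp_tot = np.asarray(comp_tot)
    denom = comp_tot.sum()
    mean_fst = float(comp_a.sum() / denom) if denom != 0.0 else 0.0
    L = len(snp_ids)
    if L > 1:
        jack = np.empty(L)
        for i in range(L):
            d = denom - comp_tot[i]
            jack[i] = (comp_a.sum() - comp_a[i]) / d if d != 0.0 else 0.0
        se = float(np.sqrt((L - 1) / L * ((jack - jack.mean()) ** 2).sum()))
    else:
        se = float("nan")
    return FstResult(snp_ids, np.asarray(per_locus), mean_fst, se, L)


# -- power / MDRR ---------------------------------------------------------

@dataclass
class PowerRequest:
    n_cases: int
    n_controls: int
    maf: float
    grr: float = 2.0
    mode: str = "multiplicative"
    alpha: float = 0.05
    n_reps: int = 5000
    seed: int = 0
    test: str = "genotypic"   # or "allelic"

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.grr < 1.0:
            raise ValueError("grr must be >= 1")
        if self.mode not in ("dominant", "recessive", "multiplicative"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _genotype_probs(maf: float, grr: float, mode: str):
    q = 1.0 - maf
    base = np.array([q * q, 2 * q * maf, maf * maf])
    if mode == "multiplicative":
        w = np.array([1.0, grr, grr * grr])
    elif mode == "dominant":
        w = np.array([1.0, grr, grr])
    else:  # recessive
        w = np.array([1.0, 1.0, grr])
    case = base * w
    return base, case / case.sum()


def _chi2_2x3(case_counts: np.ndarray, ctrl_counts: np.ndarray):
    """Vectorized Pearson chi-square over replicate 2x3 genotype tables.

    Columns with zero expected count drop out of the statistic and reduce
    the degrees of freedom for that replicate.
    """
    tot = case_counts + ctrl_counts
    n = tot.sum(axis=1, keepdims=True).astype(float)
    row_case = case_counts.sum(axis=1, keepdims=True) / n
    stat = np.zeros(case_counts.shape[0])
    nonzero = np.zeros(case_counts.shape[0], dtype=int)
    for col in range(tot.shape[1]):
        e_case = tot[:, col] * row_case[:, 0]
        e_ctrl = tot[:, col] * (1 - row_case[:, 0])
        live = tot[:, col] > 0
        nonzero += live
        stat[live] += ((case_counts[live, col] - e_case[live]) ** 2
                       / e_case[live]
                       + (ctrl_counts[live, col] - e_ctrl[live]) ** 2
                       / e_ctrl[live])
    df = np.maximum(nonzero - 1, 1)
    return stats.chi2.sf(stat, df)


def _allelic_chi2(case_counts: np.ndarray, ctrl_counts: np.ndarray):
    weights = np.array([0, 1, 2])
    a_case = case_counts @ weights
    a_ctrl = ctrl_counts @ weights
    n_case = 2 * case_counts.sum(axis=1)
    n_ctrl = 2 * ctrl_counts.sum(axis=1)
    table = np.stack([
        np.stack([a_case, n_case - a_case], axis=1),
        np.stack([a_ctrl, n_ctrl - a_ctrl], axis=1),
    ], axis=1).astype(float)
    n = table.sum(axis=(1, 2))
    rows = table.sum(axis=2)
    cols = table.sum(axis=1)
    stat = np.zeros(table.shape[0])
    for i in range(2):
        for j in range(2):
            e = rows[:, i] * cols[:, j] / n
            ok = e > 0
            stat[ok] += (table[ok, i, j] - e[ok]) ** 2 / e[ok]
    return stats.chi2.sf(stat, 1)


def power_case_control(req: PowerRequest) -> float:
    """Monte-Carlo power of the case-control genotype association test.

    Controls are drawn from Hardy-Weinberg proportions at ``maf``; cases
    from the genotype distribution distorted by the genotype relative risk
    under ``mode``. The default test is a genotypic 2x3 chi-square; an
    allelic 2x2 test is available via ``req.test``.
    """
    if req.n_reps < 100:
        raise ValueError("n_reps < 100 gives an unusably noisy estimate")
    rng = np.random.default_rng(req.seed)
    ctrl_p, case_p = _genotype_probs(req.maf, req.grr, req.mode)
    case = rng.multinomial(req.n_cases, case_p, size=req.n_reps)
    ctrl = rng.multinomial(req.n_controls, ctrl_p, size=req.n_reps)
    if req.test == "allelic":
        pvals = _allelic_chi2(case, ctrl)
    else:
        pvals = _chi2_2x3(case, ctrl)
    return float((pvals < req.alpha).mean())


def mdrr(req: PowerRequest, target_power: float = 0.85,
         grr_max: float = 10.0, tol: float = 0.02,
         max_iter: int = 40) -> dict:
    """Minimum detectable genotype relative risk by bisection on power.

    Returns the bracket midpoint once the bracket width falls below
    Monte-Carlo resolution. Common random numbers (one seed for every
    power evaluation) keep the power curve monotone in GRR.
    """
    if not req.alpha < target_power < 1.0:
        raise ValueError("target_power must lie in (alpha, 1)")

    def power_at(grr):
        r = PowerRequest(req.n_cases, req.n_controls, req.maf, grr,
                         req.mode, req.alpha, req.n_reps, req.seed,
                         req.test)
        return power_case_control(r)

    hi_power = power_at(grr_max)
    if hi_power < target_power:
        raise ValueError(
            f"target power {target_power} unreachable at grr <= {grr_max} "
            f"(power there: {hi_power:.3f})"
        )
    lo, hi = 1.0, grr_max
    mc_se = math.sqrt(target_power * (1 - target_power) / req.n_reps)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = power_at(mid)
        if abs(p - target_power) <= max(tol, 2 * mc_se) and hi - lo < 0.05:
            break
        if p < target_power:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-3:
            break
    return {"mdrr": 0.5 * (lo + hi), "bracket": (lo, hi),
            "power_at_mdrr": power_at(0.5 * (lo + hi))}
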