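"""Haplotype frequency estimation by expectation-maximization.

Unphased multi-SNP genotypes within one gene are compatible with several
ordered pairs of haplotypes; the EM algorithm weights each compatible pair
by current frequency estimates under Hardy-Weinberg pairing and
re-estimates frequencies until convergence (the classic gene-counting /
Excoffier-Slatkin scheme). The fitted object also yields per-sample
posterior distributions over haplotype pairs and max-posterior carriage
calls, the subject-level unit used by the association stage.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeDataset

logger = logging.getLogger(__name__)

PRUNE_FREQ = 1e-6


def _hap_string(hap: tuple, loci) -> str:
    return "".join(
        loc.allele_minor if bit else loc.allele_major
        for bit, loc in zip(hap, loci)
    )


def _compatible_pairs(pattern: tuple) -> list[tuple[tuple, tuple]]:
    """Unordered haplotype pairs compatible with a genotype pattern.

    ``pattern`` holds minor-allele counts in {0,1,2}. With h heterozygous
    sites there are 2^(h-1) distinct unordered pairs (1 if h == 0); the
    first het site is pinned to the major allele on the first haplotype to
    avoid double counting.
    """
    het = [i for i, c in enumerate(pattern) if c == 1]
    base = [0 if c == 0 else 1 if c == 2 else None for c in pattern]
    if not het:
        hap = tuple(base)
        return [(hap, hap)]
    pairs = []
    first, rest = het[0], het[1:]
    for bits in itertools.product((0, 1), repeat=len(rest)):
        h1, h2 = list(base), list(base)
        h1[first], h2[first] = 0, 1
        for pos, bit in zip(rest, bits):
            h1[pos], h2[pos] = bit, 1 - bit
        a, b = tuple(h1), tuple(h2)
        pairs.append((a, b) if a <= b else (b, a))
    return pairs


@dataclass
class HaplotypeEMResults:
    """Fitted per-gene haplotype model.

    ``haplotypes``/``freqs`` list the estimated haplotype spectrum (alleles
    spelled in the gene's SNP order, frequencies on the simplex).
    ``posteriors`` maps each phased-able sample to a dict over unordered
    haplotype-pair strings; support is restricted to pairs compatible with
    the observed genotype.
    """

    gene: str
    snp_order: list
    haplotypes: list[str]
    freqs: np.ndarray
    loglik: float
    posteriors: dict
    n_iter: int
    converged: bool
    sample_ids: list
    excluded_ids: list = field(default_factory=list)
    n_restarts: int = 1
    seed: int | None = None

    def frequency(self, haplotype: str) -> float:
        try:
            return float(self.freqs[self.haplotypes.index(haplotype)])
        except ValueError:
            return 0.0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.gene,
            "haplotype": self.haplotypes,
            "frequency": self.freqs,
        }).sort_values("frequency", ascending=False, ignore_index=True)


class HaplotypeEM:
    """EM model for one gene's haplotype frequencies.

    Parameters
    ----------
    geno : GenotypeDataset
        Genotypes; restricted to ``gene`` if the registry spans several.
    gene : str, optional
        Gene symbol to restrict to.

    Samples missing any SNP of the gene are excluded from the fit (and
    logged); the haplotype space is the set of haplotypes compatible with
    at least one retained sample.
    """

    def __init__(self, geno: GenotypeDataset, gene: str | None = None):
        if gene is not None:
            geno = geno.restrict_gene(gene)
        genes = {l.gene for l in geno.registry}
        if len(genes) != 1:
            raise ValueError(f"genotypes span several genes: {genes}")
        self.gene = genes.pop()
        self.loci = list(geno.registry)
        complete = (geno.codes >= 0).all(axis=1)
        self.sample_ids = [s for s, ok in zip(geno.sample_ids, complete)
                           if ok]
        self.excluded_ids = [s for s, ok in zip(geno.sample_ids, complete)
                             if not ok]
        if self.excluded_ids:
            logger.info("gene %s: %d samples with missing SNPs excluded "
                        "from EM", self.gene, len(self.excluded_ids))
        if not self.sample_ids:
            raise ValueError(f"gene {self.gene}: no complete genotypes")
        codes = geno.codes[complete]
        self.patterns, self.pattern_counts = {}, {}
        self.sample_pattern = []
        for row in codes:
            pat = tuple(int(c) for c in row)
            self.sample_pattern.append(pat)
            self.pattern_counts[pat] = self.pattern_counts.get(pat, 0) + 1
        hap_set = {}
        for pat in self.pattern_counts:
            pairs = _compatible_pairs(pat)
            self.patterns[pat] = pairs
            for a, b in pairs:
                hap_set.setdefault(a, len(hap_set))
                hap_set.setdefault(b, len(hap_set))
        self.hap_index = hap_set
        self.haplotypes = [None] * len(hap_set)
        for hap, k in hap_set.items():
            self.haplotypes[k] = hap

    # -- core EM ----------------------------------------------------------

    def _loglik_and_expected(self, freqs: np.ndarray):
        """One E-step: log-likelihood and expected haplotype counts."""
        expected = np.zeros_like(freqs)
        loglik = 0.0
        for pat, pairs in self.patterns.items():
            cnt = self.pattern_counts[pat]
            w = np.empty(len(pairs))
            for m, (a, b) in enumerate(pairs):
                i, j = self.hap_index[a], self.hap_index[b]
                w[m] = (freqs[i] * freqs[j] if i == j
                        else 2.0 * freqs[i] * freqs[j])
            tot = w.sum()
            if tot <= 0.0:
                return -np.inf, expected
            loglik += cnt * np.log(tot)
            post = w / tot
            for m, (a, b) in enumerate(pairs):
                expected[self.hap_index[a]] += cnt * post[m]
                expected[self.hap_index[b]] += cnt * post[m]
        return loglik, expected

    def _run_em(self, freqs0, tol, max_iter):
        freqs = freqs0.copy()
        prev_ll = -np.inf
        converged = False
        for it in range(1, max_iter + 1):
            ll, expected = self._loglik_and_expected(freqs)
            if ll < prev_ll - 1e-9:
                raise AssertionError(
                    f"EM log-likelihood decreased ({prev_ll} -> {ll})"
                )
            new = expected / (2.0 * len(self.sample_ids))
            if (np.max(np.abs(new - freqs)) < tol
                    or (np.isfinite(prev_ll) and ll - prev_ll < tol)):
                freqs = new
                converged = True
                break
            freqs, prev_ll = new, ll
        ll, _ = self._loglik_and_expected(freqs)
        return freqs, ll, it, converged

    def fit(self, tol: float = 1e-8, max_iter: int = 1000,
            n_restarts: int = 5, seed: int | None = 0
            ) -> HaplotypeEMResults:
        """Best-of-restarts EM fit.

        The first start is uniform over the compatible haplotype space;
        the remaining ``n_restarts - 1`` are Dirichlet(1) draws, guarding
        against local optima on multi-locus likelihoods.
        """
        K = len(self.haplotypes)
        rng = np.random.default_rng(seed)
        starts = [np.full(K, 1.0 / K)]
        for _ in range(max(0, n_restarts - 1)):
            starts.append(rng.dirichlet(np.ones(K)))
        best = None
        for f0 in starts:
            freqs, ll, it, conv = self._run_em(f0, tol, max_iter)
            if best is None or ll > best[1]:
                best = (freqs, ll, it, conv)
        freqs, ll, n_iter, converged = best
        if not converged:
            logger.warning("gene %s: EM did not converge in %d iterations",
                           self.gene, max_iter)
        posteriors = self._posteriors(freqs)
        keep = freqs >= PRUNE_FREQ
        hap_strings = [_hap_string(h, self.loci) for h in self.haplotypes]
        return HaplotypeEMResults(
            gene=self.gene,
            snp_order=[l.snp_id for l in self.loci],
            haplotypes=[h for h, k in zip(hap_strings, keep) if k],
            freqs=freqs[keep] / freqs[keep].sum(),
            loglik=float(ll),
            posteriors=posteriors,
            n_iter=n_iter,
            converged=converged,
            sample_ids=self.sample_ids,
            excluded_ids=self.excluded_ids,
            n_restarts=n_restarts,
            seed=seed,
        )

    def _posteriors(self, freqs):
        post_by_pattern = {}
        for pat, pairs in self.patterns.items():
            w = np.empty(len(pairs))
            for m, (a, b) in enumerate(pairs):
                i, j = self.hap_index[a], self.hap_index[b]
                w[m] = (freqs[i] * freqs[j] if i == j
                        else 2.0 * freqs[i] * freqs[j])
            tot = w.sum()
            w = w / tot if tot > 0 else np.full(len(pairs), 1 / len(pairs))
            post_by_pattern[pat] = {
                (_hap_string(a, self.loci), _hap_string(b, self.loci)):
                    float(p)
                for (a, b), p in zip(pairs, w)
            }
        return {
            sid: post_by_pattern[pat]
            for sid, pat in zip(self.sample_ids, self.sample_pattern)
        }


def em_haplotype_frequencies(geno: GenotypeDataset,
                             gene: str | None = None,
                             tol: float = 1e-8, max_iter: int = 1000,
                             n_restarts: int = 5,
                             seed: int | None = 0) -> HaplotypeEMResults:
    """Functional wrapper around :class:`HaplotypeEM`."""
    return HaplotypeEM(geno, gene=gene).fit(
        tol=tol, max_iter=max_iter, n_restarts=n_restarts, seed=seed)


# -- carriage -------------------------------------------------------------

class CarriageTable:
    """Best-guess haplotype copy counts per subject.

    ``copies`` is a samples x haplotypes integer DataFrame derived from
    each sample's maximum-posterior haplotype pair (ties broken toward the
    lexicographically smaller pair, deterministically). ``certainty``
    holds the posterior probability of the chosen pair, used by the
    haplotype-uncertainty fit measure.
    """

    def __init__(self, copies: pd.DataFrame, certainty: pd.Series,
                 gene: str):
        self.copies = copies
        self.certainty = certainty
        self.gene = gene

    @property
    def haplotypes(self) -> list[str]:
        return list(self.copies.columns)

    @property
    def sample_ids(self) -> list:
        return self.copies.index.tolist()

    def carriers(self, haplotype: str) -> pd.Series:
        """Boolean: carries >= 1 copy."""
        return self.copies[haplotype] >= 1

    def copy_counts(self, haplotype: str) -> pd.Series:
        return self.copies[haplotype]

    def group_summary(self, group_masks: dict) -> pd.DataFrame:
        """Carrier counts and fractions per haplotype for named groups."""
        rows = []
        for hap in self.haplotypes:
            row = {"haplotype": hap}
            carriers = self.carriers(hap).to_numpy()
            for name, mask in group_masks.items():
                mask = np.asarray(mask, dtype=bool)
                n = int(mask.sum())
                k = int(carriers[mask].sum())
                row[f"{name}_carriers"] = k
                row[f"{name}_fraction"] = k / n if n else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def drop(self, haplotypes) -> "CarriageTable":
        keep = [h for h in self.haplotypes if h not in set(haplotypes)]
        return CarriageTable(self.copies[keep], self.certainty, self.gene)


def posterior_carriage(sol: HaplotypeEMResults) -> CarriageTable:
    """Max-posterior carriage calls for every phased sample."""
    haps = list(sol.haplotypes)
    hap_pos = {h: k for k, h in enumerate(haps)}
    copies = np.zeros((len(sol.sample_ids), len(haps)), dtype=int)
    certainty = np.empty(len(sol.sample_ids))
    for i, sid in enumerate(sol.sample_ids):
        post = sol.posteriors[sid]
        best_p = max(post.values())
        ties = [pair for pair, p in post.items()
                if p >= best_p - 1e-12]
        if len(ties) > 1:
            logger.info("sample %s: %d tied max-posterior pairs; "
                        "lexicographic break", sid, len(ties))
        a, b = min(ties)
        certainty[i] = post[min(ties)]
        for h in (a, b):
            if h in hap_pos:  # pruned haplotypes carry ~0 posterior
                copies[i, hap_pos[h]] += 1
    frame = pd.DataFrame(copies, index=pd.Index(sol.sample_ids,
                                                name="sample_id"),
                         columns=haps)
    return CarriageTable(frame,
                         pd.Series(certainty, index=frame.index,
                                   name="certainty"),
                         sol.gene)


def haplotype_coverage(sol: HaplotypeEMResults, retained) -> float:
    """Summed estimated frequency of a retained haplotype subset.

    This operationalizes the "fraction of genetic variance captured" by
    the haplotypes kept for association.
    """
    retained = set(retained)
    unknown = retained - set(sol.haplotypes)
    if unknown:
        raise ValueError(f"haplotypes not in solution: {sorted(unknown)}")
    return float(sum(sol.frequency(h) for h in retained))


def filter_rare_haplotypes(carriage: CarriageTable, min_freq: float,
                           group_masks: dict,
                           criterion: str = "fraction") -> CarriageTable:
    """Drop haplotypes rare in *every* group.

    ``criterion`` "fraction" compares per-group carrier fractions with
    ``min_freq``; "count" compares raw carrier counts (both readings of a
    "frequency below five" exclusion rule are supported). A haplotype is
    kept if it reaches the threshold in at least one group.
    """
    if not 0.0 <= min_freq < 1.0 and criterion == "fraction":
        raise ValueError("min_freq must lie in [0, 1) for fractions")
    summary = carriage.group_summary(group_masks)
    drop = []
    for _, row in summary.iterrows():
        if criterion == "fraction":
            vals = [row[f"{g}_fraction"] for g in group_masks]
        elif criterion == "count":
            vals = [row[f"{g}_carriers"] for g in group_masks]
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if all(v < min_freq for v in vals):
            drop.append(row["haplotype"])
    if len(drop) == len(carriage.haplotypes):
        raise ValueError("rare-haplotype filter removed every haplotype")
    if drop:
        logger.info("gene %s: removed rare haplotypes %s",
                    carriage.gene, drop)
    return carriage.drop(drop)
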