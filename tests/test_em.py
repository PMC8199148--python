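"""Haplotype EM: frequencies, posteriors, carriage, filtering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from haplorisk.data import GenotypeDataset
from haplorisk.em import (HaplotypeEM, HaplotypeEMResults,
                          filter_rare_haplotypes, haplotype_coverage,
                          posterior_carriage)
from haplorisk.registry import Locus, LocusRegistry
from haplorisk.simulate import _hap_minor_vector, default_hap_freqs

from conftest import make_dataset, make_single_locus_dataset

TWO_SNP_LOCI = [Locus("rs0001", "CRP", "A", "G", 0),
                Locus("rs0002", "CRP", "G", "C", 1)]


def two_locus_em_oracle(codes, step=1e-3):
    """Brute-force MLE for a 2-SNP gene.

    Conditional on the gene-counting allele frequencies (which the MLE
    must match), the only free parameter is the frequency of the
    major-major haplotype; a 1-D grid search over its admissible range
    maximizes the multinomial likelihood directly.
    """
    codes = np.asarray(codes)
    n = len(codes)
    p1 = codes[:, 0].sum() / (2 * n)   # minor at SNP1
    p2 = codes[:, 1].sum() / (2 * n)
    qa, qb = 1 - p1, 1 - p2            # major allele freqs

    def loglik(f00):
        # haplotypes 00,01,10,11 (0 = major); margins pin the rest
        f = {(0, 0): f00, (0, 1): qa - f00, (1, 0): qb - f00,
             (1, 1): f00 - qa - qb + 1}
        if min(f.values()) < 0:
            return -np.inf
        ll = 0.0
        for row in codes:
            tot = 0.0
            for h1 in itertools.product((0, 1), repeat=2):
                for h2 in itertools.product((0, 1), repeat=2):
                    if (h1[0] + h2[0], h1[1] + h2[1]) == tuple(row):
                        tot += f[h1] * f[h2]
            if tot <= 0:
                return -np.inf
            ll += np.log(tot)
        return ll

    lo, hi = max(0.0, qa + qb - 1.0), min(qa, qb)
    grid = np.arange(lo, hi + step, step)
    best = grid[np.argmax([loglik(g) for g in grid])]
    return {(0, 0): best, (0, 1): qa - best, (1, 0): qb - best,
            (1, 1): best - qa - qb + 1}


class TestEMFrequencies:
    def test_all_homozygous_exact_in_one_pass(self):
        # AA/GG, AA/GG, GG/CC -> haplotypes AG, AG, GC per chromosome
        ds = make_dataset([[0, 0], [0, 0], [2, 2]], TWO_SNP_LOCI)
        sol = HaplotypeEM(ds).fit()
        assert sol.frequency("AG") == pytest.approx(2 / 3)
        assert sol.frequency("GC") == pytest.approx(1 / 3)

    def test_single_snp_gene_equals_gene_counting(self):
        ds = make_single_locus_dataset([0, 1, 1, 2, 0])
        sol = HaplotypeEM(ds).fit()
        assert sol.frequency("G") == pytest.approx(4 / 10)
        assert sol.frequency("A") == pytest.approx(6 / 10)

    def test_matches_grid_search_oracle_with_double_heterozygotes(self):
        rng = np.random.default_rng(17)
        # draw 20 samples from a known 2-SNP haplotype distribution
        freqs = np.array([0.5, 0.2, 0.2, 0.1])
        haps = [(0, 0), (0, 1), (1, 0), (1, 1)]
        idx = rng.choice(4, size=(20, 2), p=freqs)
        codes = np.array([[haps[i][0] + haps[j][0],
                           haps[i][1] + haps[j][1]] for i, j in idx])
        ds = make_dataset(codes, TWO_SNP_LOCI)
        sol = HaplotypeEM(ds).fit()
        oracle = two_locus_em_oracle(codes)
        label = {(0, 0): "AG", (0, 1): "AC", (1, 0): "GG", (1, 1): "GC"}
        for hap, f in oracle.items():
            assert sol.frequency(label[hap]) == pytest.approx(f, abs=2e-3)

    def test_freqs_and_posteriors_on_simplex(self, cohort):
        geno, _, _ = cohort
        sol = HaplotypeEM(geno, "IL6").fit(seed=0)
        assert sol.freqs.sum() == pytest.approx(1.0, abs=1e-10)
        for post in sol.posteriors.values():
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-10)

    def test_posterior_support_is_genotype_compatible(self, cohort):
        geno, _, _ = cohort
        sub = geno.restrict_gene("VDR")
        sol = HaplotypeEM(sub).fit(seed=0)
        codes = {s: sub.codes[i] for i, s in enumerate(sub.sample_ids)}
        for sid, post in sol.posteriors.items():
            for (h1, h2), p in post.items():
                if p == 0.0:
                    continue
                implied = [
                    (a != l.allele_major) + (b != l.allele_major)
                    for a, b, l in zip(h1, h2, sub.registry)
                ]
                assert implied == list(codes[sid])

    def test_missing_snp_excludes_sample_from_gene(self):
        codes = np.array([[0, 0], [1, -1], [2, 2]])
        ds = make_dataset(codes, TWO_SNP_LOCI)
        model = HaplotypeEM(ds)
        assert model.excluded_ids == ["S1"]
        with pytest.raises(ValueError, match="no complete genotypes"):
            HaplotypeEM(make_dataset([[-1, 0]], TWO_SNP_LOCI))

    def test_em_tracks_realized_sample_frequencies(self, registry):
        """Phase inference adds almost no error beyond sampling noise:
        the EM estimate stays within 0.03 of the realized (phase-known)
        haplotype frequencies of the sample."""
        loci = registry.gene_loci("VDR")
        reg = LocusRegistry(loci)
        pairs = default_hap_freqs()["VDR"]
        names = [h for h, _ in pairs]
        p = np.array([f for _, f in pairs])
        bits = np.vstack([_hap_minor_vector(h, loci) for h in names])
        rng = np.random.default_rng(11)
        for rep in range(20):
            idx = rng.choice(len(p), size=(287, 2), p=p)
            realized = np.bincount(idx.ravel(), minlength=len(p)) / 574
            codes = bits[idx[:, 0]] + bits[idx[:, 1]]
            ds = GenotypeDataset([f"S{i}" for i in range(287)], reg,
                                 codes.astype(np.int8))
            sol = HaplotypeEM(ds).fit(seed=rep, n_restarts=2)
            est = np.array([sol.frequency(h) for h in names])
            assert np.abs(est - realized).max() <= 0.03


class TestCarriage:
    def test_unambiguous_sample_carriage_is_forced(self):
        ds = make_dataset([[1, 0]], TWO_SNP_LOCI)  # single het: no phase
        carr = posterior_carriage(HaplotypeEM(ds).fit())
        assert carr.copies.loc["S0", "AG"] == 1
        assert carr.copies.loc["S0", "GG"] == 1
        assert carr.certainty.loc["S0"] == pytest.approx(1.0)

    def test_max_posterior_pair_is_chosen(self):
        sol = HaplotypeEMResults(
            gene="CRP", snp_order=["rs0001", "rs0002"],
            haplotypes=["AG", "GC", "AC", "GG"],
            freqs=np.array([0.4, 0.3, 0.2, 0.1]), loglik=0.0,
            posteriors={"S0": {("AG", "GC"): 0.9, ("AC", "GG"): 0.1}},
            n_iter=1, converged=True, sample_ids=["S0"])
        carr = posterior_carriage(sol)
        assert carr.copies.loc["S0"].to_dict() == {
            "AG": 1, "GC": 1, "AC": 0, "GG": 0}

    def test_tie_breaks_to_lexicographically_smaller_pair(self):
        sol = HaplotypeEMResults(
            gene="CRP", snp_order=["rs0001", "rs0002"],
            haplotypes=["AG", "GC", "AC", "GG"],
            freqs=np.array([0.25, 0.25, 0.25, 0.25]), loglik=0.0,
            posteriors={"S0": {("AG", "GC"): 0.5, ("AC", "GG"): 0.5}},
            n_iter=1, converged=True, sample_ids=["S0"])
        carr = posterior_carriage(sol)
        assert carr.copies.loc["S0", "AC"] == 1  # ("AC","GG") < ("AG","GC")

    def test_copy_counts_sum_to_two(self, cohort):
        geno, _, _ = cohort
        carr = posterior_carriage(HaplotypeEM(geno, "CRP").fit(seed=0))
        assert (carr.copies.sum(axis=1) == 2).all()

    def test_carrier_fraction_recovers_generating_probability(
            self, registry):
        loci = registry.gene_loci("VDR")
        pairs = default_hap_freqs()["VDR"]
        names = [h for h, _ in pairs]
        p = np.array([f for _, f in pairs])
        bits = np.vstack([_hap_minor_vector(h, loci) for h in names])
        rng = np.random.default_rng(23)
        idx = rng.choice(len(p), size=(287, 2), p=p)
        codes = bits[idx[:, 0]] + bits[idx[:, 1]]
        ds = GenotypeDataset([f"S{i}" for i in range(287)],
                             LocusRegistry(loci), codes.astype(np.int8))
        carr = posterior_carriage(HaplotypeEM(ds).fit(seed=1))
        k = names.index("AGC")
        expected = 1 - (1 - p[k]) ** 2
        observed = carr.carriers("AGC").mean()
        assert observed == pytest.approx(expected, abs=0.05)


class TestCoverageAndFilter:
    def _solution(self, haps, freqs):
        return HaplotypeEMResults(
            gene="CRP", snp_order=[], haplotypes=haps,
            freqs=np.asarray(freqs, dtype=float), loglik=0.0,
            posteriors={}, n_iter=1, converged=True, sample_ids=[])

    def test_full_and_empty_retention(self):
        sol = self._solution(["A", "B"], [0.7, 0.3])
        assert haplotype_coverage(sol, ["A", "B"]) == pytest.approx(1.0)
        assert haplotype_coverage(sol, []) == 0.0

    def test_common_haplotype_subset_lands_in_reported_band(self):
        # five retained carrier-level fractions summing to 0.90 sit in
        # the 85-95% "variance captured" band quoted for this gene family
        sol = self._solution(
            ["AGC", "GGT", "AGT", "GCT", "GCC", "RARE"],
            [0.46, 0.05, 0.24, 0.09, 0.06, 0.10])
        cov = haplotype_coverage(sol, ["AGC", "GGT", "AGT", "GCT", "GCC"])
        assert cov == pytest.approx(0.90, abs=1e-12)
        assert 0.85 <= cov <= 0.95

    def _carriage(self, case_copies, ctrl_copies, haps):
        copies = pd.DataFrame(
            np.vstack([case_copies, ctrl_copies]), columns=haps,
            index=pd.Index([f"S{i}" for i in
                            range(len(case_copies) + len(ctrl_copies))],
                           name="sample_id"))
        from haplorisk.em import CarriageTable
        masks = {"case": np.arange(len(copies)) < len(case_copies),
                 "control": np.arange(len(copies)) >= len(case_copies)}
        return CarriageTable(copies, pd.Series(1.0, index=copies.index),
                             "CRP"), masks

    def test_rare_in_both_groups_removed(self):
        case = [[2, 0]] * 96 + [[1, 1]] * 4
        ctrl = [[2, 0]] * 97 + [[1, 1]] * 3
        carr, masks = self._carriage(case, ctrl, ["COMMON", "RARE"])
        out = filter_rare_haplotypes(carr, 0.05, masks)
        assert out.haplotypes == ["COMMON"]

    def test_exact_threshold_retained(self):
        case = [[2, 0]] * 95 + [[1, 1]] * 5
        ctrl = [[2, 0]] * 100
        carr, masks = self._carriage(case, ctrl, ["COMMON", "EDGE"])
        out = filter_rare_haplotypes(carr, 0.05, masks)
        assert "EDGE" in out.haplotypes

    def test_zero_threshold_is_identity(self):
        case = [[2, 0]] * 9 + [[1, 1]]
        carr, masks = self._carriage(case, [[2, 0]] * 10, ["A", "B"])
        out = filter_rare_haplotypes(carr, 0.0, masks)
        assert out.haplotypes == ["A", "B"]

    def test_removing_everything_errors(self):
        carr, masks = self._carriage([[0, 0]] * 10, [[0, 0]] * 10,
                                     ["A", "B"])
        with pytest.raises(ValueError, match="every haplotype"):
            filter_rare_haplotypes(carr, 0.5, masks)
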