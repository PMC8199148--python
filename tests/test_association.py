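"""Logistic engine, carrier odds ratios, inheritance-mode selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from haplorisk.association import (CollinearityError, HaplotypeAssociation,
                                   InheritanceModeScan, SeparationError,
                                   bonferroni, compute_r2h,
                                   fit_logistic, odds_ratio_2x2)
from haplorisk.data import PhenotypeTable
from haplorisk.em import CarriageTable

from conftest import make_pheno_frame


def expand_2x2(a, b, c, d):
    """Per-subject (y, x) rows from a 2x2 exposure table."""
    y = np.array([1] * (a + b) + [0] * (c + d))
    x = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
    return y, x


class TestFitLogistic:
    def test_single_binary_predictor_reproduces_cross_product_or(self):
        y, x = expand_2x2(68, 130, 26, 155)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert np.exp(fit.params["x"]) == pytest.approx(3.12, abs=0.005)

    def test_null_predictor_gives_zero_coefficient(self):
        y, x = expand_2x2(50, 50, 50, 50)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-8)
        assert abs(fit.zvalues["x"]) < 0.01

    def test_loglik_matches_direct_maximization_oracle(self):
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        X = pd.DataFrame({"x1": [0.5, -1, 2, 0, 1, -2, 1.5, 0.2],
                          "x2": [1, 0, 1, 0, 0, 1, 1, 0.0]})
        fit = fit_logistic(y, X)

        Xm = np.column_stack([np.ones(8), X.to_numpy()])

        def nll(beta):
            eta = Xm @ beta
            return -(y @ eta - np.logaddexp(0, eta).sum())

        res = minimize(nll, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_aic_identity(self):
        y, x = expand_2x2(30, 20, 10, 40)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
        assert fit.k == 2

    def test_separation_raises_unless_firth(self):
        y = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        x = y.astype(float)  # perfectly separating
        with pytest.raises(SeparationError):
            fit_logistic(y, pd.DataFrame({"x": x}))
        fit = fit_logistic(y, pd.DataFrame({"x": x}), firth="auto")
        assert fit.separation and fit.method == "firth"
        assert np.isfinite(fit.params["x"])

    def test_collinear_design_rejected(self):
        y, x = expand_2x2(30, 20, 10, 40)
        X = pd.DataFrame({"x": x, "x_copy": x})
        with pytest.raises(CollinearityError):
            fit_logistic(y, X)
        with pytest.raises(CollinearityError, match="zero"):
            fit_logistic(y, pd.DataFrame({"x": x, "z": 0.0 * x}))


class TestOddsRatio:
    @pytest.mark.parametrize("cells,expected", [
        ((68, 130, 26, 155), (3.12, 1.88, 5.19)),
        ((43, 65, 21, 71), (2.24, 1.20, 4.16)),
    ])
    def test_woolf_interval_reproduction(self, cells, expected):
        assert odds_ratio_2x2(*cells).round2() == expected

    def test_balanced_table_is_symmetric_about_one(self):
        r = odds_ratio_2x2(10, 10, 10, 10)
        assert r.odds_ratio == pytest.approx(1.0)
        assert np.log(r.ci_low) == pytest.approx(-np.log(r.ci_high))

    def test_zero_cell_triggers_continuity_correction(self):
        r = odds_ratio_2x2(0, 10, 5, 10)
        assert r.continuity and np.isfinite(r.odds_ratio)

    def test_logistic_and_cross_product_agree_on_any_2x2(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a, b, c, d = rng.integers(5, 80, 4)
            y, x = expand_2x2(a, b, c, d)
            fit = fit_logistic(y, pd.DataFrame({"x": x}))
            assert np.exp(fit.params["x"]) == pytest.approx(
                (a * d) / (b * c), rel=1e-6)


class TestBonferroni:
    def test_arithmetic_and_capping(self):
        assert bonferroni([0.01]) == [0.01]
        assert bonferroni([0.01, 0.2, 0.5]) == pytest.approx(
            [0.03, 0.6, 1.0])

    def test_order_preserved(self):
        ps = [0.04, 0.001, 0.3, 0.02]
        out = bonferroni(ps)
        assert np.argsort(out).tolist() == np.argsort(ps).tolist()


def build_carriage(case_counts, ctrl_counts, n_case, n_ctrl,
                   referent="AGC", overlap=True):
    """Carriage table reproducing given per-group carrier counts.

    With ``overlap`` each non-referent carrier also carries the referent
    (the printed carrier margins count such subjects on both sides); with
    ``overlap=False`` non-referent carriers are haplotype homozygotes.
    """
    haps = [referent] + [h for h in case_counts if h != referent]
    rows, status = [], []
    for counts, n, st in ((case_counts, n_case, 1),
                          (ctrl_counts, n_ctrl, 0)):
        used = 0
        for hap in haps[1:]:
            for _ in range(counts[hap]):
                extra = {hap: 1, referent: 1} if overlap else {hap: 2}
                rows.append({h: 0 for h in haps} | extra)
                status.append(st)
                used += 1
        n_ref_only = counts[referent]
        if overlap:
            n_ref_only -= sum(counts[h] for h in haps[1:])
        for _ in range(n_ref_only):
            rows.append({h: 0 for h in haps} | {referent: 2})
            status.append(st)
            used += 1
        for _ in range(n - used):   # carriers of unlisted haplotypes
            rows.append({h: 0 for h in haps})
            status.append(st)
    copies = pd.DataFrame(rows,
                          index=pd.Index([f"S{i}" for i in
                                          range(len(rows))],
                                         name="sample_id"))
    carr = CarriageTable(copies, pd.Series(1.0, index=copies.index),
                         "CRP")
    pheno = PhenotypeTable(make_pheno_frame(status))
    return carr, pheno


class TestHaplotypeAssociation:
    def test_carrier_table_odds_ratios_match_published_counts(self):
        case = {"AGC": 130, "GGT": 14, "AGT": 68, "GCT": 26, "GCC": 18}
        ctrl = {"AGC": 155, "GGT": 21, "AGT": 26, "GCT": 20, "GCC": 24}
        carr, pheno = build_carriage(case, ctrl, 279, 287)
        res = HaplotypeAssociation(carr, pheno, referent="AGC",
                                   covariates=()).fit()
        ors = {r.haplotype: round(r.unadjusted.odds_ratio, 2)
               for r in res.rows}
        assert ors == {"GGT": 0.79, "AGT": 3.12, "GCT": 1.55,
                       "GCC": 0.89}
        agt = next(r for r in res.rows if r.haplotype == "AGT")
        assert (agt.case_carriers, agt.case_referent,
                agt.control_carriers, agt.control_referent) == \
            (68, 130, 26, 155)

    def test_most_prevalent_haplotype_is_default_referent(self):
        case = {"AGC": 130, "AGT": 68}
        ctrl = {"AGC": 155, "AGT": 26}
        carr, pheno = build_carriage(case, ctrl, 279, 287)
        res = HaplotypeAssociation(carr, pheno, covariates=()).fit()
        assert res.referent == "AGC"

    def test_missing_referent_rejected(self):
        case = {"AGC": 10, "AGT": 5}
        carr, pheno = build_carriage(case, case, 20, 20)
        with pytest.raises(ValueError, match="referent"):
            HaplotypeAssociation(carr, pheno, referent="XXX")

    def test_constant_covariates_leave_or_unchanged(self):
        case = {"AGC": 130, "AGT": 68}
        ctrl = {"AGC": 155, "AGT": 26}
        carr, pheno = build_carriage(case, ctrl, 279, 287, overlap=False)
        pheno.frame["BMI"] = 26.0   # dichotomizes to all-zero indicator
        res = HaplotypeAssociation(carr, pheno,
                                   covariates=("BMI",)).fit()
        row = res.rows[0]
        assert row.adjusted_or == pytest.approx(
            row.unadjusted.odds_ratio, rel=1e-6)

    def test_confounder_explains_away_association(self):
        """Carriage driven entirely by a dichotomized covariate: the
        adjusted OR collapses toward 1 while the unadjusted OR stays
        inflated."""
        rng = np.random.default_rng(5)
        n = 2000
        conf = rng.binomial(1, 0.5, n)
        carrier = rng.binomial(1, 0.1 + 0.6 * conf)
        p_case = 1 / (1 + np.exp(-(-1.5 + 2.0 * conf)))
        status = rng.binomial(1, p_case)
        copies = pd.DataFrame(
            {"REF": 1, "HAP": carrier},
            index=pd.Index([f"S{i}" for i in range(n)],
                           name="sample_id"))
        carr = CarriageTable(copies, pd.Series(1.0, index=copies.index),
                             "CRP")
        pheno = PhenotypeTable(make_pheno_frame(
            status, IL6=np.where(conf == 1, 5.0, 1.0)))
        res = HaplotypeAssociation(carr, pheno, referent="REF",
                                   covariates=("IL6",)).fit()
        row = res.rows[0]
        assert row.unadjusted.odds_ratio > 1.4
        assert row.adjusted_or == pytest.approx(1.0, abs=0.25)

    def test_bonferroni_scope_is_gene_family(self):
        case = {"AGC": 130, "GGT": 14, "AGT": 68, "GCT": 26, "GCC": 18}
        ctrl = {"AGC": 155, "GGT": 21, "AGT": 26, "GCT": 20, "GCC": 24}
        carr, pheno = build_carriage(case, ctrl, 279, 287)
        res = HaplotypeAssociation(carr, pheno, referent="AGC",
                                   covariates=()).fit()
        for r in res.rows:
            assert r.bonferroni_p == pytest.approx(
                min(1.0, r.unadjusted.p * 4))


class TestInheritanceModes:
    @staticmethod
    def simulate_copies(n, p, beta, mode, seed, intercept=-1.0):
        rng = np.random.default_rng(seed)
        copies = rng.binomial(2, p, n)
        enc = {"dominant": (copies >= 1), "recessive": (copies == 2),
               "multiplicative": copies}[mode]
        prob = 1 / (1 + np.exp(-(intercept + beta * enc)))
        status = rng.binomial(1, prob)
        return (pd.Series(copies, name="HAP",
                          index=[f"S{i}" for i in range(n)]),
                PhenotypeTable(make_pheno_frame(status)))

    def test_encoding_identity_multiplicative_is_dominant_plus_recessive(
            self):
        from haplorisk.association import MODE_ENCODERS
        c = np.array([0, 1, 2, 1, 0, 2])
        np.testing.assert_array_equal(
            MODE_ENCODERS["multiplicative"](c),
            MODE_ENCODERS["dominant"](c) + MODE_ENCODERS["recessive"](c))

    def test_null_effect_keeps_modes_close(self):
        copies, pheno = self.simulate_copies(800, 0.3, 0.0,
                                             "multiplicative", seed=1)
        copies.index = pheno.sample_ids
        scan = InheritanceModeScan(copies, pheno, covariates=()).fit()
        aics = list(scan.aic_by_mode.values())
        assert max(aics) - min(aics) < 8
        for mode in ("dominant", "recessive", "multiplicative"):
            assert abs(scan.fits[mode].beta) < 0.5

    def test_dominant_data_recovers_generating_beta(self):
        hits = 0
        for rep in range(10):
            copies, pheno = self.simulate_copies(600, 0.3, 1.0,
                                                 "dominant", seed=100 + rep)
            copies.index = pheno.sample_ids
            scan = InheritanceModeScan(copies, pheno, covariates=()).fit()
            f = scan.fits["dominant"]
            hits += abs(f.beta - 1.0) <= 2 * f.se
        assert hits >= 7

    def test_missing_copy_class_skips_general_and_recessive(self):
        copies = pd.Series([0, 1, 0, 1, 1, 0, 1, 0] * 10, name="HAP")
        status = ([0, 1] * 40)
        pheno = PhenotypeTable(make_pheno_frame(status))
        copies.index = pheno.sample_ids
        scan = InheritanceModeScan(copies, pheno, covariates=()).fit()
        assert "general" in scan.skipped
        assert "recessive" in scan.skipped

    def test_best_mode_attains_minimum_aic(self):
        copies, pheno = self.simulate_copies(600, 0.3, 1.5, "recessive",
                                             seed=9)
        copies.index = pheno.sample_ids
        scan = InheritanceModeScan(copies, pheno, covariates=()).fit()
        assert scan.aic_by_mode[scan.best_mode] == min(
            scan.aic_by_mode.values())


class TestR2h:
    def test_perfect_prediction_with_certain_phase_is_one(self):
        y = np.array([1] * 20 + [0] * 20)
        x = y.astype(float)
        fit = fit_logistic(y, pd.DataFrame({"x": x}), firth="always")
        r = compute_r2h(fit, certainty=np.ones(40))
        assert r.value == pytest.approx(1.0, abs=0.05)

    def test_unrelated_haplotype_scores_near_zero(self):
        rng = np.random.default_rng(4)
        y = rng.binomial(1, 0.5, 400)
        x = rng.binomial(1, 0.3, 400).astype(float)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert compute_r2h(fit).value < 0.05

    def test_halving_certainty_halves_certainty_factor(self):
        y, x = expand_2x2(30, 20, 10, 40)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        full = compute_r2h(fit, certainty=np.ones(100))
        half = compute_r2h(fit, certainty=np.full(100, 0.5))
        assert half.certainty_factor == pytest.approx(
            full.certainty_factor / 2)
        assert half.value == pytest.approx(full.value / 2)
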