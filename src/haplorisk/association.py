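"""Case-control association engine.

Covers the unadjusted carrier odds ratios with Woolf confidence intervals,
covariate-adjusted logistic models, Bonferroni correction, and the
inheritance-mode ladder (dominant / recessive / multiplicative / general
encodings of haplotype copy number) compared by Wald statistics, AIC and a
haplotype-uncertainty fit measure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import DichotomizationRules, PhenotypeTable, dichotomize
from .em import CarriageTable

logger = logging.getLogger(__name__)

#: Covariates used for adjustment throughout the analysis (dichotomized).
ADJUSTMENT_COVARIATES = ("BMI", "TG", "sleep", "IL6", "IL1B", "HSCRP")


class SeparationError(RuntimeError):
    pass


class CollinearityError(ValueError):
    pass


# -- logistic engine ------------------------------------------------------

@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit (optionally Firth-penalized)."""

    params: pd.Series
    bse: pd.Series
    loglik: float
    loglik_null: float
    n: int
    converged: bool
    method: str = "mle"
    separation: bool = False

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({
            "low": self.params - z * self.bse,
            "high": self.params + z * self.bse,
        })

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.params, "se": self.bse, "z": self.zvalues,
            "p": self.pvalues, "OR": np.exp(self.params),
        })


def _design(X, add_intercept: bool) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    if add_intercept and "const" not in X.columns:
        X = sm.add_constant(X, has_constant="add")
    return X


def fit_logistic(y, X, max_iter: int = 100, tol: float = 1e-8,
                 add_intercept: bool = True,
                 firth: str = "never") -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    Standard errors come from the observed information. Quasi-complete
    separation is detected (diverging coefficients) and raised as
    :class:`SeparationError` unless ``firth`` is "auto" or "always", in
    which case a Firth-penalized fit is substituted and flagged.
    """
    X = _design(X, add_intercept)
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("y and X lengths differ")
    if len(y) <= X.shape[1]:
        raise ValueError("more parameters than observations")
    zero_cols = [c for c in X.columns if (X[c] == 0).all()]
    if zero_cols:
        raise CollinearityError(f"constant-zero columns: {zero_cols}")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        sds = X.std()
        suspects = [c for c in X.columns
                    if c != "const" and sds[c] == 0.0]
        raise CollinearityError(
            f"design matrix is rank-deficient (suspect columns: "
            f"{suspects or list(X.columns)})"
        )
    if firth == "always":
        return _fit_firth(y, X, max_iter, tol)
    model = sm.Logit(y, X)
    try:
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            res = model.fit(disp=0, maxiter=max_iter, tol=tol,
                            warn_convergence=False)
        separated = bool(np.abs(res.params).max() > 15.0)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        res, separated = None, True
    if separated:
        if firth == "auto":
            logger.warning("separation detected; Firth fallback used")
            fit = _fit_firth(y, X, max_iter, tol)
            fit.separation = True
            return fit
        raise SeparationError(
            "quasi-complete separation: coefficients diverge "
            "(rerun with firth='auto' for a penalized fit)"
        )
    return LogisticFit(
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        loglik=float(res.llf),
        loglik_null=float(res.llnull),
        n=len(y),
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def _fit_firth(y, X, max_iter, tol) -> LogisticFit:
    """Firth's bias-reduced logistic fit (Jeffreys-prior penalty)."""
    Xm = X.to_numpy()
    beta = np.zeros(Xm.shape[1])
    ll = -np.inf
    converged = False
    for _ in range(max_iter * 5):
        eta = np.clip(Xm @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        XtW = Xm.T * W
        info = XtW @ Xm
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", Xm, info_inv, Xm) * W
        score = Xm.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        sign, logdet = np.linalg.slogdet(info)
        ll_new = float(
            np.sum(y * eta - np.log1p(np.exp(eta))) + 0.5 * logdet
        )
        if abs(ll_new - ll) < tol and np.max(np.abs(step)) < 1e-5:
            converged = True
            ll = ll_new
            break
        ll = ll_new
    eta = np.clip(Xm @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    info = (Xm.T * (p * (1 - p))) @ Xm
    bse = np.sqrt(np.diag(np.linalg.pinv(info)))
    ll_unpen = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    pbar = y.mean()
    ll0 = float(len(y) * (pbar * math.log(pbar + 1e-300)
                          + (1 - pbar) * math.log(1 - pbar + 1e-300)))
    return LogisticFit(
        params=pd.Series(beta, index=X.columns),
        bse=pd.Series(bse, index=X.columns),
        loglik=ll_unpen,
        loglik_null=ll0,
        n=len(y),
        converged=converged,
        method="firth",
    )


# -- 2x2 odds ratio -------------------------------------------------------

@dataclass
class OddsRatio2x2:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    continuity: bool = False

    def round2(self) -> tuple[float, float, float]:
        return (round(self.odds_ratio, 2), round(self.ci_low, 2),
                round(self.ci_high, 2))


def odds_ratio_2x2(a: int, b: int, c: int, d: int,
                   alpha: float = 0.05) -> OddsRatio2x2:
    """Cross-product odds ratio with Woolf CI and Pearson chi-square p.

    ``a``/``b`` are exposed/unexposed cases, ``c``/``d`` the controls.
    Any zero cell triggers the Haldane-Anscombe +0.5 correction on all
    four cells (flagged in the result).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be nonnegative")
    continuity = bool((cells == 0).any())
    if continuity:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    orr = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = stats.norm.ppf(1 - alpha / 2)
    table = np.array([[a, b], [c, d]], dtype=float)
    if continuity:
        table = table + 0.5
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return OddsRatio2x2(
        odds_ratio=orr,
        ci_low=math.exp(math.log(orr) - z * se),
        ci_high=math.exp(math.log(orr) + z * se),
        p=float(p),
        continuity=continuity,
    )


def bonferroni(p_values) -> list[float]:
    """Multiply each p by the family size, capping at 1."""
    m = len(p_values)
    return [min(1.0, float(p) * m) for p in p_values]


# -- haplotype association ------------------------------------------------

@dataclass
class HaplotypeAssocRow:
    haplotype: str
    referent: str
    case_carriers: int
    control_carriers: int
    case_referent: int
    control_referent: int
    unadjusted: OddsRatio2x2
    adjusted_or: float | None
    adjusted_ci: tuple | None
    adjusted_p: float | None
    bonferroni_p: float | None = None
    flag: str | None = None


@dataclass
class HaplotypeAssociationResults:
    gene: str
    referent: str
    covariates: tuple
    rows: list[HaplotypeAssocRow]

    def summary(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({
                "gene": self.gene,
                "haplotype": r.haplotype,
                "referent": r.referent,
                "case_carriers": r.case_carriers,
                "control_carriers": r.control_carriers,
                "OR": r.unadjusted.odds_ratio,
                "OR_low": r.unadjusted.ci_low,
                "OR_high": r.unadjusted.ci_high,
                "p": r.unadjusted.p,
                "adj_OR": r.adjusted_or,
                "adj_low": r.adjusted_ci[0] if r.adjusted_ci else None,
                "adj_high": r.adjusted_ci[1] if r.adjusted_ci else None,
                "adj_p": r.adjusted_p,
                "bonferroni_p": r.bonferroni_p,
                "flag": r.flag,
            })
        return pd.DataFrame(recs)


class HaplotypeAssociation:
    """Carrier-based case-control association for one gene's haplotypes.

    Each non-referent haplotype is compared with the referent (the most
    prevalent haplotype) on a carriers-versus-referent-carriers 2x2 table;
    a subject carrying both contributes to both margins. The adjusted
    estimate refits a logistic model of status on the haplotype-carriage
    indicator plus the dichotomized adjustment covariates, restricted to
    carriers of the haplotype or the referent.
    """

    def __init__(self, carriage: CarriageTable, pheno: PhenotypeTable,
                 referent: str | None = None,
                 covariates=ADJUSTMENT_COVARIATES,
                 rules: DichotomizationRules | None = None):
        self.carriage = carriage
        self.pheno = pheno
        self.covariates = tuple(covariates)
        self.rules = rules or DichotomizationRules()
        status = pheno.frame.loc[carriage.sample_ids, "status"]
        self.status = status.to_numpy(dtype=int)
        if referent is None:
            counts = {h: int(carriage.carriers(h).sum())
                      for h in carriage.haplotypes}
            referent = max(sorted(counts), key=counts.get)
        if referent not in carriage.haplotypes:
            raise ValueError(f"referent {referent!r} not in carriage table")
        self.referent = referent

    def fit(self, firth: str = "auto") -> HaplotypeAssociationResults:
        carr = self.carriage
        case = self.status == 1
        ctrl = ~case
        ref_car = carr.carriers(self.referent).to_numpy()
        indicators = dichotomize(self.pheno, self.rules,
                                 self.covariates).loc[carr.sample_ids]
        rows = []
        for hap in carr.haplotypes:
            if hap == self.referent:
                continue
            hap_car = carr.carriers(hap).to_numpy()
            a = int((hap_car & case).sum())
            b = int((ref_car & case).sum())
            c = int((hap_car & ctrl).sum())
            d = int((ref_car & ctrl).sum())
            unadj = odds_ratio_2x2(a, b, c, d)
            flag = "continuity" if unadj.continuity else None
            subset = hap_car | ref_car
            adj_or = adj_ci = adj_p = None
            try:
                X = indicators[subset].copy()
                X.insert(0, "haplotype", hap_car[subset].astype(float))
                ok = ~X.isna().any(axis=1)
                X = X[ok]
                constant = [col for col in X.columns
                            if col != "haplotype" and X[col].nunique() <= 1]
                if constant:
                    logger.info("gene %s haplotype %s: covariates %s "
                                "constant in subset; dropped",
                                carr.gene, hap, constant)
                    X = X.drop(columns=constant)
                fit = fit_logistic(self.status[subset][ok.to_numpy()],
                                   X, firth=firth)
                beta = fit.params["haplotype"]
                ci = fit.conf_int().loc["haplotype"]
                adj_or = float(np.exp(beta))
                adj_ci = (float(np.exp(ci["low"])),
                          float(np.exp(ci["high"])))
                adj_p = float(fit.pvalues["haplotype"])
                if fit.separation:
                    flag = (flag + ";firth") if flag else "firth"
            except (SeparationError, CollinearityError, ValueError) as exc:
                flag = (flag + ";" if flag else "") + f"degenerate:{exc}"
                logger.warning("gene %s haplotype %s: adjusted model "
                               "degenerate (%s)", carr.gene, hap, exc)
            rows.append(HaplotypeAssocRow(
                haplotype=hap, referent=self.referent,
                case_carriers=a, control_carriers=c,
                case_referent=b, control_referent=d,
                unadjusted=unadj,
                adjusted_or=adj_or, adjusted_ci=adj_ci, adjusted_p=adj_p,
                flag=flag,
            ))
        corrected = bonferroni([r.unadjusted.p for r in rows])
        for r, cp in zip(rows, corrected):
            r.bonferroni_p = cp
        return HaplotypeAssociationResults(
            gene=carr.gene, referent=self.referent,
            covariates=self.covariates, rows=rows)


# -- inheritance modes ----------------------------------------------------

MODE_ENCODERS = {
    "dominant": lambda c: (c >= 1).astype(float),
    "recessive": lambda c: (c == 2).astype(float),
    "multiplicative": lambda c: c.astype(float),
}


@dataclass
class InheritanceFit:
    mode: str
    beta: float
    se: float
    wald: float
    p: float
    r2h: float
    aic: float
    pseudo_r2: float
    certainty_factor: float
    fit: LogisticFit = field(repr=False, default=None)


@dataclass
class ModelSelectionResults:
    haplotype: str
    fits: dict            # mode -> InheritanceFit ("general0"/"general1")
    best_mode: str
    aic_by_mode: dict
    r2h_by_mode: dict
    agreement: bool       # min-AIC mode also attains max R2h
    skipped: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        recs = []
        for mode, f in self.fits.items():
            recs.append({
                "haplotype": self.haplotype, "mode": mode,
                "beta": f.beta, "se": f.se, "wald": f.wald, "p": f.p,
                "r2h": f.r2h, "aic": f.aic,
                "best": mode.startswith(self.best_mode),
            })
        return pd.DataFrame(recs)


@dataclass
class R2h:
    value: float
    pseudo_r2: float
    certainty_factor: float


def compute_r2h(fit: LogisticFit, certainty=None) -> R2h:
    """Haplotype-uncertainty fit measure.

    The Nagelkerke pseudo-R2 of the haplotype model, attenuated by the
    mean posterior certainty of the carriage calls that entered the
    design (1.0 when phase is unambiguous or no posteriors are supplied).
    """
    n = fit.n
    cs = 1.0 - math.exp(min(0.0, 2.0 * (fit.loglik_null - fit.loglik) / n))
    denom = 1.0 - math.exp(2.0 * fit.loglik_null / n)
    nagelkerke = cs / denom if denom > 0 else 0.0
    factor = 1.0 if certainty is None else float(np.mean(certainty))
    return R2h(value=min(1.0, nagelkerke * factor),
               pseudo_r2=nagelkerke, certainty_factor=factor)


class InheritanceModeScan:
    """Fit all inheritance encodings for one haplotype's copy counts.

    Parameters
    ----------
    copies : Series of {0, 1, 2}
        Best-guess copy counts, indexed by sample_id.
    pheno : PhenotypeTable
    covariates : names of adjustment covariates (dichotomized).
    certainty : optional per-sample posterior certainty for the
        haplotype-uncertainty attenuation of the fit measure.
    """

    def __init__(self, copies: pd.Series, pheno: PhenotypeTable,
                 covariates=ADJUSTMENT_COVARIATES,
                 certainty: pd.Series | None = None,
                 rules: DichotomizationRules | None = None):
        self.copies = copies.astype(int)
        self.pheno = pheno
        self.covariates = tuple(covariates)
        self.certainty = certainty
        self.rules = rules or DichotomizationRules()

    def _fit_one(self, cols: dict, y, certainty, firth):
        X = pd.DataFrame(cols)
        if self.covariates:
            ind = dichotomize(self.pheno, self.rules,
                              self.covariates).loc[self.copies.index]
            ind = ind.loc[:, ind.nunique() > 1]  # drop constant indicators
            X = pd.concat([X, ind.reset_index(drop=True)], axis=1)
        ok = ~X.isna().any(axis=1).to_numpy()
        fit = fit_logistic(y[ok], X[ok], firth=firth)
        cert = None if certainty is None else np.asarray(certainty)[ok]
        return fit, compute_r2h(fit, cert)

    def fit(self, firth: str = "auto") -> ModelSelectionResults:
        y = self.pheno.frame.loc[self.copies.index, "status"] \
            .to_numpy(dtype=int)
        c = self.copies.to_numpy()
        fits: dict[str, InheritanceFit] = {}
        skipped = {}
        aic_by_mode, r2h_by_mode = {}, {}
        for mode, enc in MODE_ENCODERS.items():
            col = enc(c)
            if col.std() == 0.0:
                skipped[mode] = "encoding is constant in this sample"
                logger.warning("mode %s skipped: %s", mode, skipped[mode])
                continue
            fit, r2h = self._fit_one({"hap": col}, y, self.certainty,
                                     firth)
            beta = float(fit.params["hap"])
            se = float(fit.bse["hap"])
            fits[mode] = InheritanceFit(
                mode=mode, beta=beta, se=se, wald=beta / se,
                p=float(fit.pvalues["hap"]), r2h=r2h.value, aic=fit.aic,
                pseudo_r2=r2h.pseudo_r2,
                certainty_factor=r2h.certainty_factor, fit=fit)
            aic_by_mode[mode] = fit.aic
            r2h_by_mode[mode] = r2h.value
        if all((c == k).sum() > 0 for k in (0, 1, 2)):
            fit, r2h = self._fit_one(
                {"hap1": (c == 1).astype(float),
                 "hap2": (c == 2).astype(float)}, y, self.certainty,
                firth)
            for term, label in (("hap1", "general0"), ("hap2", "general1")):
                beta = float(fit.params[term])
                se = float(fit.bse[term])
                fits[label] = InheritanceFit(
                    mode=label, beta=beta, se=se, wald=beta / se,
                    p=float(fit.pvalues[term]), r2h=r2h.value,
                    aic=fit.aic, pseudo_r2=r2h.pseudo_r2,
                    certainty_factor=r2h.certainty_factor, fit=fit)
            aic_by_mode["general"] = fit.aic
            r2h_by_mode["general"] = r2h.value
        else:
            skipped["general"] = "not all three copy classes observed"
            logger.warning("general mode skipped: %s", skipped["general"])
        if not aic_by_mode:
            raise ValueError("no inheritance mode could be fitted")
        best = min(sorted(aic_by_mode), key=aic_by_mode.get)
        best_r2h = max(sorted(r2h_by_mode), key=r2h_by_mode.get)
        agreement = best == best_r2h
        if not agreement:
            logger.info("mode selection: min-AIC %s vs max-R2h %s",
                        best, best_r2h)
        name = (self.copies.name if isinstance(self.copies.name, str)
                else "haplotype")
        return ModelSelectionResults(
            haplotype=name, fits=fits, best_mode=best,
            aic_by_mode=aic_by_mode, r2h_by_mode=r2h_by_mode,
            agreement=agreement, skipped=skipped)


def fit_inheritance_models(copies, pheno, covariates=ADJUSTMENT_COVARIATES,
                           certainty=None, firth="auto"
                           ) -> ModelSelectionResults:
    """Functional wrapper around :class:`InheritanceModeScan`."""
    return InheritanceModeScan(copies, pheno, covariates,
                               certainty).fit(firth=firth)
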