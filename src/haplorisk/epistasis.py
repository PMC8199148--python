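"""Two-locus epistasis scan against quantitative risk traits.

Each SNP is coded on an additive axis a in {-1, 0, +1} (minor-allele count
centred at the heterozygote) and a dominance axis d in {-1/2, +1/2, -1/2}
for {hom-major, het, hom-minor}. A least-squares fit of the trait on both
main axes plus the four products a1a2, a1d2, d1a2, d1d2 partitions the
interaction into additive x additive (AA), additive x dominance (AD),
dominance x additive (DA) and dominance x dominance (DD) components; the
joint 4-df F-test of all products is the overall interaction ("I") test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeDataset, PhenotypeTable

logger = logging.getLogger(__name__)

COMPONENTS = ("AA", "AD", "DA", "DD")
_PRODUCT_OF = {"AA": ("a1", "a2"), "AD": ("a1", "d2"),
               "DA": ("d1", "a2"), "DD": ("d1", "d2")}


@dataclass
class ComponentTest:
    estimate: float
    f_stat: float
    p: float
    testable: bool = True


@dataclass
class EpistasisResult:
    snp1: str
    snp2: str
    trait: str
    group: str
    n: int
    components: dict            # "AA"/"AD"/"DA"/"DD" -> ComponentTest
    overall_p: float
    overall_f: float
    overall_df: int
    collapsed: bool = False
    bonferroni: dict = field(default_factory=dict)

    def component_p(self, name: str) -> float:
        t = self.components[name]
        return t.p if t.testable else np.nan


def _additive_dominance(codes: np.ndarray, min_cell: int):
    """(a, d, collapsed?) codes after small-class collapsing.

    Genotype classes with fewer than ``min_cell`` members merge into the
    neighbouring class on the additive axis (hom classes into the het;
    an undersized het into its larger hom neighbour).
    """
    codes = codes.copy()
    collapsed = False
    counts = {k: int((codes == k).sum()) for k in (0, 1, 2)}
    for k in (0, 2):
        if 0 < counts[k] < min_cell:
            codes[codes == k] = 1
            collapsed = True
    counts = {k: int((codes == k).sum()) for k in (0, 1, 2)}
    if 0 < counts[1] < min_cell and (counts[0] or counts[2]):
        target = 0 if counts[0] >= counts[2] else 2
        codes[codes == 1] = target
        collapsed = True
    present = sorted({int(k) for k in np.unique(codes)})
    if len(present) < 2:
        return None, None, collapsed
    a = codes.astype(float) - 1.0
    d = np.where(codes == 1, 0.5, -0.5)
    if len(present) == 2:
        d = None  # dominance axis aliased with the additive axis
    return a, d, collapsed


def _ols_f_tests(y: np.ndarray, cols: dict):
    """Least-squares fit with per-column and joint product F-tests.

    Columns aliased with earlier ones (empty joint genotype classes, e.g.
    under strong within-gene LD) are dropped greedily and reported as
    untestable rather than zero.
    """
    candidates = list(cols)
    X = np.ones((len(y), 1))
    names = []
    for c in candidates:
        trial = np.column_stack([X, cols[c]])
        if np.linalg.matrix_rank(trial) > X.shape[1]:
            X = trial
            names.append(c)
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - p
    if df_resid <= 0:
        return None
    sigma2 = resid @ resid / df_resid
    if sigma2 <= 0:
        return None
    cov = sigma2 * np.linalg.inv(X.T @ X)
    out = {}
    for i, name in enumerate(names, start=1):
        t = beta[i] / np.sqrt(cov[i, i])
        f = t * t
        out[name] = ComponentTest(
            estimate=float(beta[i]), f_stat=float(f),
            p=float(stats.f.sf(f, 1, df_resid)))
    prod = [i for i, name in enumerate(names, start=1)
            if name.startswith(("a1a2", "a1d2", "d1a2", "d1d2"))]
    if prod:
        main = [i for i in range(p) if i not in prod]
        Xr = X[:, main]
        beta_r, _, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
        rss_r = float(np.sum((y - Xr @ beta_r) ** 2))
        rss_f = float(resid @ resid)
        df_num = len(prod)
        f_all = ((rss_r - rss_f) / df_num) / sigma2
        p_all = float(stats.f.sf(f_all, df_num, df_resid))
    else:
        f_all, p_all, df_num = np.nan, np.nan, 0
    return out, float(f_all), p_all, df_num


class TwoLocusEpistasisScan:
    """Scan SNP pairs x traits within one sample group.

    Parameters
    ----------
    geno, pheno : aligned cohort tables.
    traits : list of numeric phenotype columns (the PSQI sleep score is
        used as a continuous trait here).
    group_mask : boolean sample mask (e.g. cases only).
    min_cell : minimum genotype-class size before collapsing.
    pairs : optional list of (snp_id, snp_id); default all pairs.
    """

    def __init__(self, geno: GenotypeDataset, pheno: PhenotypeTable,
                 traits, group_mask=None, group: str = "cases",
                 min_cell: int = 5, pairs=None):
        self.geno = geno
        self.pheno = pheno
        self.traits = list(traits)
        self.group = group
        if group_mask is None:
            group_mask = (pheno.case_mask if group == "cases"
                          else pheno.control_mask)
        self.group_mask = np.asarray(group_mask, dtype=bool)
        self.min_cell = min_cell
        self.pairs = pairs or list(
            itertools.combinations(geno.registry.snp_ids(), 2))

    def fit(self) -> "EpistasisScanResults":
        results = []
        for snp1, snp2 in self.pairs:
            c1 = self.geno.column(snp1)[self.group_mask]
            c2 = self.geno.column(snp2)[self.group_mask]
            obs = (c1 >= 0) & (c2 >= 0)
            for trait in self.traits:
                yv = pd.to_numeric(
                    self.pheno.frame[trait], errors="coerce"
                ).to_numpy(dtype=float)[self.group_mask]
                keep = obs & ~np.isnan(yv)
                res = self._fit_pair(snp1, snp2, c1[keep], c2[keep],
                                     yv[keep], trait)
                if res is not None:
                    results.append(res)
        n_tests = len(results)
        for r in results:
            r.bonferroni = {
                "overall": min(1.0, r.overall_p * n_tests)
                if np.isfinite(r.overall_p) else np.nan,
                **{k: (min(1.0, r.components[k].p * n_tests)
                       if r.components[k].testable else np.nan)
                   for k in COMPONENTS if k in r.components},
            }
        return EpistasisScanResults(results=results, n_tests=n_tests,
                                    group=self.group,
                                    min_cell=self.min_cell)

    def _fit_pair(self, snp1, snp2, c1, c2, y, trait):
        a1, d1, col1 = _additive_dominance(c1, self.min_cell)
        a2, d2, col2 = _additive_dominance(c2, self.min_cell)
        if a1 is None or a2 is None:
            logger.info("pair (%s, %s): monomorphic after collapsing; "
                        "skipped", snp1, snp2)
            return None
        cols = {"a1": a1, "a2": a2}
        if d1 is not None:
            cols["d1"] = d1
        if d2 is not None:
            cols["d2"] = d2
        product_cols = {}
        for name, (u, v) in _PRODUCT_OF.items():
            if u in cols and v in cols:
                product_cols[name] = cols[u] * cols[v]
        design = dict(cols)
        for name, col in product_cols.items():
            design["".join(_PRODUCT_OF[name])] = col
        fitted = _ols_f_tests(y, design)
        if fitted is None:
            logger.info("pair (%s, %s) x %s: rank-deficient design; "
                        "skipped", snp1, snp2, trait)
            return None
        tests, f_all, p_all, df_num = fitted
        components = {}
        for name in COMPONENTS:
            key = "".join(_PRODUCT_OF[name])
            if key in tests:
                components[name] = tests[key]
            else:
                components[name] = ComponentTest(np.nan, np.nan, np.nan,
                                                 testable=False)
        return EpistasisResult(
            snp1=snp1, snp2=snp2, trait=trait, group=self.group,
            n=len(y), components=components,
            overall_p=p_all, overall_f=f_all, overall_df=df_num,
            collapsed=col1 or col2)


@dataclass
class EpistasisScanResults:
    results: list[EpistasisResult]
    n_tests: int
    group: str
    min_cell: int

    def summary(self) -> pd.DataFrame:
        recs = []
        for r in self.results:
            rec = {"snp1": r.snp1, "snp2": r.snp2, "trait": r.trait,
                   "group": r.group, "n": r.n,
                   "overall_p": r.overall_p,
                   "overall_p_corrected": r.bonferroni.get("overall")}
            for name in COMPONENTS:
                t = r.components[name]
                rec[f"{name}_estimate"] = t.estimate
                rec[f"{name}_p"] = t.p if t.testable else np.nan
            recs.append(rec)
        return pd.DataFrame(recs)


def classify_epistasis_mode(result: EpistasisResult,
                            alpha: float = 0.05,
                            corrected: bool = True) -> str:
    """Label a pair's interaction: the smallest significant component,
    "I" when only the joint test rejects, "none" otherwise."""
    def pval(key):
        if corrected and result.bonferroni:
            return result.bonferroni.get(key, np.nan)
        if key == "overall":
            return result.overall_p
        return result.component_p(key)

    sig = {k: pval(k) for k in COMPONENTS
           if np.isfinite(pval(k)) and pval(k) < alpha}
    if sig:
        return min(sorted(sig), key=sig.get)
    p_all = pval("overall")
    if np.isfinite(p_all) and p_all < alpha:
        return "I"
    return "none"


def export_interaction_network(scan: EpistasisScanResults,
                               geno: GenotypeDataset,
                               alpha: float = 0.05, path=None):
    """Significant pairs as a SNP graph (GraphML text when ``path`` set).

    Nodes are SNPs annotated with their gene; edges carry the trait, the
    epistasis mode label and the corrected p-value.
    """
    import networkx as nx

    graph = nx.MultiGraph()  # one edge per significant (pair, trait) test
    for locus in geno.registry:
        graph.add_node(locus.snp_id, gene=locus.gene)
    n_edges = 0
    for r in scan.results:
        mode = classify_epistasis_mode(r, alpha)
        p_corr = r.bonferroni.get("overall", np.nan)
        sig = any(
            np.isfinite(r.bonferroni.get(k, np.nan))
            and r.bonferroni[k] < alpha
            for k in (*COMPONENTS, "overall")
        )
        if not sig:
            continue
        n_edges += 1
        graph.add_edge(r.snp1, r.snp2, trait=r.trait, mode=mode,
                       p_corrected=float(min(
                           v for v in r.bonferroni.values()
                           if np.isfinite(v))))
    logger.info("interaction network: %d nodes, %d significant edges",
                graph.number_of_nodes(), n_edges)
    if path is not None:
        nx.write_graphml(graph, path)
    return graph
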