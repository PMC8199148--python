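"""End-to-end pipeline orchestration with a reproducibility manifest.

A single configuration (dict or YAML file) drives the stage order
popgen -> haplotypes -> association -> epistasis -> risk_roc on either a
simulated cohort or genotype/phenotype CSVs; every stage writes its
tables under the run directory and the manifest records the config
snapshot, seeds, package version and per-file checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (ADJUSTMENT_COVARIATES, HaplotypeAssociation,
                          InheritanceModeScan)
from .data import (DichotomizationRules, dichotomize, read_genotypes,
                   read_phenotypes, write_genotypes, write_phenotypes)
from .em import HaplotypeEM, filter_rare_haplotypes, posterior_carriage
from .epistasis import TwoLocusEpistasisScan, export_interaction_network
from .popgen import maf_by_gene_counting, pairwise_fst
from .registry import default_registry
from .risk import build_haplotype_grs, model_ladder
from .simulate import CohortSpec, simulate_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = ("popgen", "haplotypes", "association", "epistasis",
              "risk_roc")

DEFAULT_TRAITS = ("IL6", "IL1B", "HSCRP", "TG", "LDL", "BMI", "sleep")

DEFAULT_LADDER = [
    ("TRD1", ["BMI", "TG", "sleep"]),
    ("TRD2", ["BMI", "sleep"]),
    ("TRD2+IL6+IL1B", ["BMI", "sleep", "IL6", "IL1B"]),
    ("TRD2+IL6+IL1B+HSCRP", ["BMI", "sleep", "IL6", "IL1B", "HSCRP"]),
    ("TRD2+IL6+IL1B+GRS", ["BMI", "sleep", "IL6", "IL1B",
                           "GRS_GGGGCT", "GRS_AGC"]),
]

DEFAULT_GRS_HAPLOTYPES = [("IL6", "GGGGCT"), ("VDR", "AGC")]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _validate_config(config: dict) -> dict:
    known = {"seed", "output_dir", "stages", "simulate", "genotypes",
             "phenotypes", "haplotypes", "association", "epistasis",
             "risk_roc"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    stages = config.get("stages", list(ALL_STAGES))
    bad = set(stages) - set(ALL_STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    if "simulate" not in config and (
            "genotypes" not in config or "phenotypes" not in config):
        raise ValueError(
            "config needs either a 'simulate' block or both 'genotypes' "
            "and 'phenotypes' paths")
    return config


def run_pipeline(config, output_dir=None) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = _validate_config(dict(config))
    seed = int(config.get("seed", 0))
    out = Path(output_dir or config.get("output_dir", "haplorisk_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ALL_STAGES))
    registry = default_registry()
    rules = DichotomizationRules()
    manifest = {"version": __version__, "seed": seed,
                "config": {k: v for k, v in config.items()},
                "stages_run": [], "stages_skipped": [],
                "outputs": {}, "warnings": []}

    def emit(name: str, frame: pd.DataFrame):
        path = out / name
        frame.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = _sha256(path)

    # -- inputs ----------------------------------------------------------
    if "simulate" in config:
        spec = CohortSpec(seed=seed, **(config["simulate"] or {}))
        geno, pheno, truth = simulate_cohort(spec, registry, rules)
        write_genotypes(geno, out / "genotypes.csv")
        write_phenotypes(pheno, out / "phenotypes.csv")
        manifest["outputs"]["genotypes.csv"] = _sha256(
            out / "genotypes.csv")
        manifest["outputs"]["phenotypes.csv"] = _sha256(
            out / "phenotypes.csv")
        manifest["achieved_prevalence"] = truth["achieved_prevalence"]
    else:
        geno = read_genotypes(config["genotypes"], registry)
        pheno = read_phenotypes(config["phenotypes"])
        if not pheno.aligned_with(geno):
            raise ValueError("genotype and phenotype sample_ids differ")
    case, ctrl = pheno.case_mask, pheno.control_mask

    # -- popgen ----------------------------------------------------------
    if "popgen" in stages:
        recs = []
        for group, mask in (("all", None), ("case", case),
                            ("control", ctrl)):
            for s in maf_by_gene_counting(geno, mask, group):
                recs.append(vars(s))
        emit("locus_stats.tsv", pd.DataFrame(recs))
        fst = pairwise_fst(geno, case, ctrl)
        (out / "fst.json").write_text(json.dumps({
            "mean_fst": fst.mean_fst, "se": fst.se,
            "n_loci": fst.n_loci_used,
            "per_locus": dict(zip(fst.snp_ids,
                                  fst.per_locus_fst.tolist())),
        }, indent=2))
        manifest["outputs"]["fst.json"] = _sha256(out / "fst.json")
        manifest["stages_run"].append("popgen")
    else:
        manifest["stages_skipped"].append("popgen")

    # -- haplotypes ------------------------------------------------------
    carriages = {}
    if {"haplotypes", "association", "risk_roc"} & set(stages):
        hap_cfg = config.get("haplotypes") or {}
        min_freq = float(hap_cfg.get("min_freq", 0.05))
        hap_rows = []
        for gene in registry.genes:
            sol = HaplotypeEM(geno, gene).fit(seed=seed)
            carr = posterior_carriage(sol)
            keep = np.isin(pheno.sample_ids, carr.sample_ids)
            masks = {"case": case[keep], "control": ctrl[keep]}
            carr = filter_rare_haplotypes(carr, min_freq, masks)
            carriages[gene] = (sol, carr, masks)
            summ = carr.group_summary(masks)
            summ.insert(0, "gene", gene)
            summ["frequency"] = [sol.frequency(h)
                                 for h in summ["haplotype"]]
            hap_rows.append(summ)
        if "haplotypes" in stages:
            emit("haplotypes.tsv", pd.concat(hap_rows, ignore_index=True))
            manifest["stages_run"].append("haplotypes")
    if "haplotypes" not in stages:
        manifest["stages_skipped"].append("haplotypes")

    # -- association -----------------------------------------------------
    if "association" in stages:
        cov = tuple((config.get("association") or {}).get(
            "covariates", ADJUSTMENT_COVARIATES))
        assoc_rows, mode_rows = [], []
        for gene, (sol, carr, masks) in carriages.items():
            sub = pheno.frame.loc[carr.sample_ids]
            sub_pheno = type(pheno)(sub)
            res = HaplotypeAssociation(carr, sub_pheno,
                                       covariates=cov).fit()
            assoc_rows.append(res.summary())
            rows = [r for r in res.rows if r.adjusted_p is not None]
            if rows:
                top = min(rows, key=lambda r: r.adjusted_p)
                scan = InheritanceModeScan(
                    carr.copy_counts(top.haplotype), sub_pheno,
                    covariates=cov, certainty=carr.certainty).fit()
                mode_rows.append(scan.summary().assign(gene=gene))
        emit("association.tsv", pd.concat(assoc_rows, ignore_index=True))
        if mode_rows:
            emit("inheritance_modes.tsv",
                 pd.concat(mode_rows, ignore_index=True))
        manifest["stages_run"].append("association")
    else:
        manifest["stages_skipped"].append("association")

    # -- epistasis -------------------------------------------------------
    if "epistasis" in stages:
        epi_cfg = config.get("epistasis") or {}
        traits = list(epi_cfg.get("traits", DEFAULT_TRAITS))
        group = epi_cfg.get("group", "cases")
        alpha = float(epi_cfg.get("alpha", 0.05))
        scan = TwoLocusEpistasisScan(geno, pheno, traits,
                                     group=group).fit()
        emit("epistasis.tsv", scan.summary())
        export_interaction_network(scan, geno, alpha,
                                   path=out / "epistasis_network.graphml")
        manifest["outputs"]["epistasis_network.graphml"] = _sha256(
            out / "epistasis_network.graphml")
        manifest["stages_run"].append("epistasis")
    else:
        manifest["stages_skipped"].append("epistasis")

    # -- risk scores & ROC ladder ---------------------------------------
    if "risk_roc" in stages:
        roc_cfg = config.get("risk_roc") or {}
        grs_haps = roc_cfg.get("grs_haplotypes", DEFAULT_GRS_HAPLOTYPES)
        ladder_spec = roc_cfg.get("ladder", DEFAULT_LADDER)
        features = dichotomize(pheno, rules)
        for gene, hap in grs_haps:
            grs = build_haplotype_grs(geno, hap, gene, registry)
            features[f"GRS_{hap}"] = grs.scores
        ladder = model_ladder(pheno, features,
                              [(n, list(c)) for n, c in ladder_spec])
        emit("roc_ladder.tsv", ladder.summary())
        if len(ladder.comparisons):
            emit("roc_comparisons.tsv", ladder.comparisons)
        manifest["stages_run"].append("risk_roc")
    else:
        manifest["stages_skipped"].append("risk_roc")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest
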