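"""Cohort data model and tabular I/O.

Genotypes are unphased, unordered allele pairs at biallelic SNPs; they are
stored internally as minor-allele counts (0/1/2, -1 = missing) against a
:class:`~haplorisk.registry.LocusRegistry`. Phenotypes are a per-sample
case/control status plus the clinical and biochemical covariates used for
adjustment and risk scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import Locus, LocusRegistry

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"./.", "NA", "", "NaN", "nan", None}

#: Canonical phenotype column order for CSV round-trips.
PHENOTYPE_COLUMNS = [
    "sample_id", "status", "BMI", "SBP", "DBP", "TC", "TG", "LDL",
    "sleep", "smoker", "alcohol", "IL6", "IL1B", "TNFA", "HSCRP",
]

_NONNEGATIVE = ["BMI", "SBP", "DBP", "TC", "TG", "LDL", "sleep",
                "IL6", "IL1B", "TNFA", "HSCRP"]


class GenotypeValidationError(ValueError):
    pass


class GenotypeDataset:
    """Samples x loci unordered allele-pair calls.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample labels.
    registry : LocusRegistry
        Ordered locus definitions; the call matrix columns follow it.
    codes : ndarray of int8, shape (n_samples, n_loci)
        Minor-allele copy counts; -1 marks a missing call.
    """

    def __init__(self, sample_ids, registry: LocusRegistry, codes):
        self.sample_ids = list(sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        self.registry = registry
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(self.sample_ids), len(registry)):
            raise ValueError(
                f"codes shape {codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(registry)} loci"
            )
        if codes.min(initial=0) < -1 or codes.max(initial=0) > 2:
            raise GenotypeValidationError("codes must lie in {-1,0,1,2}")
        self.codes = codes

    # -- construction -----------------------------------------------------

    @classmethod
    def from_calls(cls, sample_ids, registry: LocusRegistry, calls):
        """Build from string calls like ``"A/G"`` (order-free) or missing."""
        calls = np.asarray(calls, dtype=object)
        codes = np.full(calls.shape, -1, dtype=np.int8)
        for j, locus in enumerate(registry):
            for i in range(calls.shape[0]):
                codes[i, j] = _parse_call(calls[i, j], locus, sample_ids[i])
        return cls(sample_ids, registry, codes)

    # -- views ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.registry)

    def locus_index(self, snp_id: str) -> int:
        loc = self.registry.get(snp_id)
        return self.registry.loci.index(loc)

    def column(self, snp_id: str) -> np.ndarray:
        """Minor-allele counts for one SNP."""
        return self.codes[:, self.locus_index(snp_id)]

    def restrict_gene(self, gene: str) -> "GenotypeDataset":
        """Sub-dataset with only one gene's SNPs (haplotype order)."""
        loci = self.registry.gene_loci(gene)
        idx = [self.registry.loci.index(l) for l in loci]
        return GenotypeDataset(
            self.sample_ids, LocusRegistry(loci), self.codes[:, idx]
        )

    def subset(self, mask) -> "GenotypeDataset":
        mask = np.asarray(mask)
        ids = [s for s, keep in zip(self.sample_ids, mask) if keep]
        return GenotypeDataset(ids, self.registry, self.codes[mask])

    def call_strings(self) -> pd.DataFrame:
        """Calls as "maj/min"-style strings (major allele written first)."""
        out = {}
        for j, locus in enumerate(self.registry):
            a, b = locus.allele_major, locus.allele_minor
            rep = {-1: "./.", 0: f"{a}/{a}", 1: f"{a}/{b}", 2: f"{b}/{b}"}
            out[locus.snp_id] = [rep[int(c)] for c in self.codes[:, j]]
        return pd.DataFrame(out, index=pd.Index(self.sample_ids,
                                                name="sample_id"))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeDataset)
            and self.sample_ids == other.sample_ids
            and self.registry.snp_ids() == other.registry.snp_ids()
            and np.array_equal(self.codes, other.codes)
        )


def _parse_call(raw, locus: Locus, sample_id) -> int:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return -1
    token = str(raw).strip()
    if token in MISSING_TOKENS:
        return -1
    parts = token.split("/")
    if len(parts) != 2:
        raise GenotypeValidationError(
            f"sample {sample_id!r}, locus {locus.snp_id}: "
            f"malformed call {token!r}"
        )
    count = 0
    for allele in parts:
        if allele in (".",):
            return -1
        if allele == locus.allele_minor:
            count += 1
        elif allele != locus.allele_major:
            raise GenotypeValidationError(
                f"sample {sample_id!r}, locus {locus.snp_id}: allele "
                f"{allele!r} not in registered pair "
                f"{locus.allele_major}/{locus.allele_minor}"
            )
    return count


# -- genotype CSV ---------------------------------------------------------

def read_genotypes(path, registry: LocusRegistry) -> GenotypeDataset:
    """Read a genotype CSV (``sample_id`` column then one column per rsID).

    Cells are unordered "X/Y" pairs or a missing token ("./." or "NA").
    Columns may appear in any order but every header must be a registered
    rsID; allele symbols are validated against the registry.
    """
    frame = pd.read_csv(path, dtype=str)
    if "sample_id" not in frame.columns:
        raise ValueError("genotype file lacks a sample_id column")
    if len(frame) == 0:
        raise ValueError("no samples in genotype file")
    for col in frame.columns:
        if col != "sample_id" and col not in registry:
            raise KeyError(f"snp_id {col!r} not in registry")
    sample_ids = frame["sample_id"].tolist()
    calls = np.empty((len(frame), len(registry)), dtype=object)
    for j, locus in enumerate(registry):
        if locus.snp_id in frame.columns:
            calls[:, j] = frame[locus.snp_id].to_numpy(dtype=object)
        else:
            logger.warning("registry SNP %s absent from %s; calls set "
                           "missing", locus.snp_id, path)
            calls[:, j] = None
    ds = GenotypeDataset.from_calls(sample_ids, registry, calls)
    n_obs = int((ds.codes >= 0).sum())
    logger.info("read %d samples x %d loci (%d observed calls) from %s",
                len(ds), ds.n_loci, n_obs, path)
    return ds


def write_genotypes(dataset: GenotypeDataset, path) -> None:
    dataset.call_strings().to_csv(path)


def import_vcf(path, registry: LocusRegistry) -> GenotypeDataset:
    """Import biallelic SNP GT calls from a VCF; phase is discarded.

    Records are matched to the registry by their ID field. A multiallelic
    record matching a registered SNP is an error; registered SNPs absent
    from the file become missing calls with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    codes = np.full((len(sample_ids), len(registry)), -1, dtype=np.int8)
    seen = set()
    snp_index = {l.snp_id: j for j, l in enumerate(registry)}
    for variant in vcf:
        if variant.ID not in snp_index:
            continue
        if len(variant.ALT) != 1:
            raise ValueError(
                f"registry SNP {variant.ID} is multiallelic in {path}"
            )
        j = snp_index[variant.ID]
        locus = registry.loci[j]
        allele_of = {0: variant.REF, 1: variant.ALT[0]}
        for i, gt in enumerate(variant.genotypes):  # [a, b, phased]
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            count = 0
            for idx in (a, b):
                allele = allele_of[idx]
                if allele == locus.allele_minor:
                    count += 1
                elif allele != locus.allele_major:
                    raise GenotypeValidationError(
                        f"sample {sample_ids[i]!r}, locus {locus.snp_id}: "
                        f"VCF allele {allele!r} not registered"
                    )
            codes[i, j] = count
        seen.add(variant.ID)
    for snp_id in snp_index:
        if snp_id not in seen:
            logger.warning("registry SNP %s absent from VCF %s",
                           snp_id, path)
    return GenotypeDataset(sample_ids, registry, codes)


# -- phenotypes -----------------------------------------------------------

class PhenotypeTable:
    """Per-sample case/control status and covariates.

    Wraps a DataFrame indexed by ``sample_id`` with a binary ``status``
    column (1 = case) and the covariate columns of
    :data:`PHENOTYPE_COLUMNS`.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.name != "sample_id":
            if "sample_id" not in frame.columns:
                raise ValueError("phenotype table lacks sample_id")
            frame = frame.set_index("sample_id")
        if len(frame) == 0:
            raise ValueError("no samples in phenotype table")
        if "status" not in frame.columns:
            raise ValueError("phenotype table lacks a status column")
        status = frame["status"].astype(float)
        if not status.isin([0.0, 1.0]).all():
            bad = sorted(set(status) - {0.0, 1.0})
            raise ValueError(f"non-binary status values: {bad}")
        frame["status"] = status.astype(int)
        for col in _NONNEGATIVE:
            if col in frame.columns:
                vals = pd.to_numeric(frame[col], errors="coerce")
                if (vals.dropna() < 0).any():
                    raise ValueError(f"negative values in covariate {col}")
                frame[col] = vals
        if frame.index.duplicated().any():
            raise ValueError("duplicate sample_ids in phenotype table")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list:
        return self.frame.index.tolist()

    @property
    def status(self) -> np.ndarray:
        return self.frame["status"].to_numpy(dtype=int)

    @property
    def case_mask(self) -> np.ndarray:
        return self.status == 1

    @property
    def control_mask(self) -> np.ndarray:
        return self.status == 0

    def covariate(self, name: str) -> pd.Series:
        return self.frame[name]

    def aligned_with(self, geno: GenotypeDataset) -> bool:
        return self.sample_ids == geno.sample_ids


def read_phenotypes(path) -> PhenotypeTable:
    frame = pd.read_csv(path)
    return PhenotypeTable(frame)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    cols = [c for c in PHENOTYPE_COLUMNS if c != "sample_id"
            and c in pheno.frame.columns]
    extra = [c for c in pheno.frame.columns if c not in cols]
    pheno.frame[cols + extra].to_csv(path)


# -- dichotomization ------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    """Single-threshold indicator rule.

    ``direction`` is the comparison that yields indicator 1: "gt" (value >
    threshold) or "ge" (value >= threshold).
    """

    threshold: float
    direction: str = "gt"

    def apply(self, values: pd.Series) -> pd.Series:
        if self.direction == "gt":
            ind = values > self.threshold
        elif self.direction == "ge":
            ind = values >= self.threshold
        else:
            raise ValueError(f"unknown direction {self.direction!r}")
        out = ind.astype(float)
        out[values.isna()] = np.nan
        return out


@dataclass
class DichotomizationRules:
    """Per-covariate indicator thresholds.

    Defaults follow the grouped logistic models of the source cohort:
    SBP >120, DBP >80, TC >200, LDL >100, TG >150, PSQI sleep score >=5,
    IL-6 / IL-1b / TNF-a >3 pg/mL, hsCRP >3 mg/L. BMI was reported as a
    "<25 vs >=30" contrast, which leaves 25-30 kg/m2 unassigned; the
    default single-cutoff reading scores BMI >= 30 as 1 (configurable).
    """

    rules: dict = field(default_factory=lambda: {
        "SBP": Rule(120, "gt"),
        "DBP": Rule(80, "gt"),
        "BMI": Rule(30, "ge"),
        "TC": Rule(200, "gt"),
        "LDL": Rule(100, "gt"),
        "TG": Rule(150, "gt"),
        "sleep": Rule(5, "ge"),
        "IL6": Rule(3, "gt"),
        "IL1B": Rule(3, "gt"),
        "TNFA": Rule(3, "gt"),
        "HSCRP": Rule(3, "gt"),
    })

    def __getitem__(self, name: str) -> Rule:
        return self.rules[name]


def dichotomize(pheno: PhenotypeTable,
                rules: DichotomizationRules | None = None,
                covariates=None) -> pd.DataFrame:
    """0/1 indicator matrix for the requested covariates.

    Missing covariate values propagate as NaN indicators; model fits drop
    such samples listwise.
    """
    rules = rules or DichotomizationRules()
    names = list(covariates) if covariates is not None else [
        c for c in rules.rules if c in pheno.frame.columns
    ]
    out = {}
    for name in names:
        if name not in rules.rules:
            raise KeyError(f"no dichotomization rule for covariate {name}")
        if name not in pheno.frame.columns:
            raise KeyError(f"covariate {name} absent from phenotype table")
        out[name] = rules[name].apply(
            pd.to_numeric(pheno.frame[name], errors="coerce"))
    return pd.DataFrame(out, index=pheno.frame.index)
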