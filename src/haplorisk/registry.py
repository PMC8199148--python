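"""Locus registry for the 20-SNP inflammatory-gene panel.

The default registry covers five genes implicated in knee-osteoarthritis
risk — CRP, COL1A1, IL6, VDR and ENOS — with the SNPs of each gene kept in
the order used to spell that gene's haplotype strings (e.g. the CRP
haplotype ``AGT`` reads rs2794521=A, rs1800947=G, rs1130864=T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

GENES = ("CRP", "COL1A1", "IL6", "VDR", "ENOS")

#: rsID typos seen in the literature, mapped to their canonical identifiers.
SNP_ALIASES = {
    "rs18008593": "rs1808593",
    "rs391881": "rs3918181",
}


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP within a gene's haplotype block.

    ``gene_order_index`` is the 0-based position of this SNP's allele in the
    gene's haplotype string.
    """

    snp_id: str
    gene: str
    allele_major: str
    allele_minor: str
    gene_order_index: int

    def __post_init__(self) -> None:
        if self.allele_major == self.allele_minor:
            raise ValueError(
                f"{self.snp_id}: major and minor allele are both "
                f"{self.allele_major!r}"
            )

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.allele_major, self.allele_minor))


class LocusRegistry:
    """Ordered collection of :class:`Locus` records with per-gene lookup."""

    def __init__(self, loci: list[Locus]):
        self.loci = list(loci)
        self._by_id = {}
        seen = set()
        for loc in self.loci:
            if loc.snp_id in self._by_id:
                raise ValueError(f"duplicate snp_id {loc.snp_id}")
            key = (loc.gene, loc.gene_order_index)
            if key in seen:
                raise ValueError(
                    f"duplicate gene_order_index {loc.gene_order_index} "
                    f"within gene {loc.gene}"
                )
            seen.add(key)
            self._by_id[loc.snp_id] = loc

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __contains__(self, snp_id: str) -> bool:
        return self._canonical(snp_id) in self._by_id

    @staticmethod
    def _canonical(snp_id: str) -> str:
        if snp_id in SNP_ALIASES:
            warnings.warn(
                f"snp_id {snp_id!r} mapped to canonical "
                f"{SNP_ALIASES[snp_id]!r}",
                stacklevel=3,
            )
            return SNP_ALIASES[snp_id]
        return snp_id

    def get(self, snp_id: str) -> Locus:
        snp_id = self._canonical(snp_id)
        try:
            return self._by_id[snp_id]
        except KeyError:
            raise KeyError(f"snp_id {snp_id!r} not in registry") from None

    @property
    def genes(self) -> list[str]:
        out = []
        for loc in self.loci:
            if loc.gene not in out:
                out.append(loc.gene)
        return out

    def gene_loci(self, gene: str) -> list[Locus]:
        """SNPs of one gene, in haplotype-string order."""
        loci = sorted(
            (l for l in self.loci if l.gene == gene),
            key=lambda l: l.gene_order_index,
        )
        if not loci:
            raise KeyError(f"gene {gene!r} not in registry")
        return loci

    def snp_ids(self) -> list[str]:
        return [l.snp_id for l in self.loci]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LocusRegistry":
        loci = [
            Locus(
                snp_id=str(r.snp_id),
                gene=str(r.gene),
                allele_major=str(r.allele_major),
                allele_minor=str(r.allele_minor),
                gene_order_index=int(r.gene_order_index),
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(loci)

    @classmethod
    def from_csv(cls, path) -> "LocusRegistry":
        return cls.from_frame(pd.read_csv(path))


def default_registry() -> LocusRegistry:
    """The packaged 20-SNP, five-gene panel."""
    path = resources.files("haplorisk").joinpath("resources/loci.csv")
    with path.open() as fh:
        return LocusRegistry.from_csv(fh)
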