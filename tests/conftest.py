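import numpy as np
import pandas as pd
import pytest

from haplorisk import CohortSpec, GenotypeDataset, simulate_cohort
from haplorisk.registry import Locus, LocusRegistry, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across read-only tests."""
    return simulate_cohort(CohortSpec(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(CohortSpec(n_cases=80, n_controls=80, seed=5))


def make_single_locus_dataset(codes, snp_id="rs0001", gene="CRP",
                              major="A", minor="G"):
    reg = LocusRegistry([Locus(snp_id, gene, major, minor, 0)])
    ids = [f"S{i}" for i in range(len(codes))]
    return GenotypeDataset(ids, reg,
                           np.asarray(codes, dtype=np.int8)[:, None])


def make_dataset(codes, loci):
    reg = LocusRegistry(loci)
    ids = [f"S{i}" for i in range(len(codes))]
    return GenotypeDataset(ids, reg, np.asarray(codes, dtype=np.int8))


def make_pheno_frame(status, **covs):
    n = len(status)
    frame = pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)],
                          "status": status})
    for name, vals in covs.items():
        frame[name] = vals
    return frame
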