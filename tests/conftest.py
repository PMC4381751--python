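import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rarecnv import SampleSheet, SnpManifest

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_manifest() -> SnpManifest:
    """Ten evenly spaced SNPs on one chromosome, moderate PFB."""
    n = 10
    return SnpManifest(pd.DataFrame({
        "snp_id": [f"snp{i}" for i in range(n)],
        "chrom": "chr1",
        "pos_bp": np.arange(1, n + 1) * 1000,
        "gc_fraction": 0.5,
        "pfb": 0.3,
    }))


@pytest.fixture(scope="session")
def two_chrom_manifest() -> SnpManifest:
    """Two chromosomes, 60 + 40 SNPs, 25 kb spacing."""
    rows = []
    for chrom, n in (("chr1", 60), ("chr2", 40)):
        for i in range(n):
            rows.append((f"{chrom}_s{i}", chrom, (i + 1) * 25_000, 0.5, 0.4))
    return SnpManifest(pd.DataFrame(rows, columns=[
        "snp_id", "chrom", "pos_bp", "gc_fraction", "pfb"]))


def make_sheet(sample_ids, phenotypes=None, plates=None, cohorts=None,
               dna_sources=None) -> SampleSheet:
    n = len(sample_ids)
    return SampleSheet(pd.DataFrame({
        "sample_id": list(sample_ids),
        "phenotype": phenotypes if phenotypes is not None else ["control"] * n,
        "plate_id": plates if plates is not None else ["p0"] * n,
        "cohort_id": cohorts if cohorts is not None else ["c0"] * n,
        "dna_source": dna_sources if dna_sources is not None else ["genomic"] * n,
        "sex": "unknown",
    }))


@pytest.fixture
def sheet_factory():
    return make_sheet
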