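import numpy as np
import pytest

from rangecoal.demography import DemeSpec, DemographicModel
from rangecoal.filtering import GenotypeMatrix


def make_gm(genotypes, coverage=None, sites=None, demes=None, loci=None, snp_ids=None):
    """Build a GenotypeMatrix from a plain (n_samples, n_snps) genotype array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    if coverage is None:
        coverage = np.full((n, m), 20, dtype=np.int32)
    if sites is None:
        sites = np.array([f"S{i // 2 + 1}" for i in range(n)], dtype=object)
    if demes is None:
        demes = np.array(["D1" if i < n // 2 else "D2" for i in range(n)], dtype=object)
    if loci is None:
        loci = np.array([f"L{j + 1}" for j in range(m)], dtype=object)
    if snp_ids is None:
        snp_ids = np.array([f"{loc}:10" for loc in loci], dtype=object)
    return GenotypeMatrix(
        samples=[f"ind{i + 1}" for i in range(n)],
        sites=np.asarray(sites, dtype=object),
        demes=np.asarray(demes, dtype=object),
        loci=np.asarray(loci, dtype=object),
        snp_ids=np.asarray(snp_ids, dtype=object),
        genotypes=g,
        coverage=np.asarray(coverage, dtype=np.int32),
    )


def one_deme_model(N=1000.0, n=4, name="A"):
    return DemographicModel(
        name=f"one-deme-{name}",
        demes=[DemeSpec(name, float(N), n)],
        events=[],
        migration={},
        params=[],
    )


@pytest.fixture
def gm_factory():
    return make_gm
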