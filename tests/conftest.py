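import numpy as np
import pytest
from hypothesis import settings

from ldpanel.core import GenotypeMatrix, SampleMeta, SnpRecord
from ldpanel.simulate import SimConfig, simulate_population

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_matrix(calls, snps=None, samples=None):
    """GenotypeMatrix from a nested list of dosages (-1 = no-call)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if snps is None:
        snps = [
            SnpRecord(name=f"snp{j}", chromosome="1", position=1000 * (j + 1),
                      alleles=("A", "G"))
            for j in range(m)
        ]
    if samples is None:
        samples = [SampleMeta(id=f"s{i}") for i in range(n)]
    return GenotypeMatrix(samples, snps, calls)


@pytest.fixture(scope="session")
def small_pop():
    """A small two-chromosome population with pedigree and known truth."""
    cfg = SimConfig(
        n_chromosomes=2,
        n_snps_per_chrom=300,
        n_founders=30,
        n_generations=2,
        offspring_per_generation=60,
        genotyping_error_rate=0.0,
        nocall_rate=0.0,
        seed=7,
    )
    return simulate_population(cfg)
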