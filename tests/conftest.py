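import numpy as np
import pytest

from sweepscan.io import HaplotypeMatrix


def make_matrix(alleles, polarized=True, positions=None, chrom="1"):
    """HaplotypeMatrix from a sites x haplotypes array with synthetic metadata."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_sites, n_hap = alleles.shape
    assert n_hap % 2 == 0
    if positions is None:
        positions = 100 * (np.arange(n_sites) + 1)
    return HaplotypeMatrix(
        alleles=alleles,
        positions=np.asarray(positions),
        site_ids=np.array([f"{chrom}:{p}" for p in positions], dtype=object),
        chrom=np.full(n_sites, chrom, dtype=object),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        sample_ids=np.array([f"s{i}" for i in range(n_hap // 2)], dtype=object),
        polarized=polarized,
    )


def random_matrix(rng, n_sites, n_samples, missing_frac=0.0, polarized=True):
    alleles = rng.integers(0, 2, size=(n_sites, 2 * n_samples)).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random(alleles.shape) < missing_frac
        alleles[mask] = -1
    return make_matrix(alleles, polarized=polarized)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
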