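import numpy as np
import pytest

from haplosweep.types import HaplotypePanel, SnpMeta


def make_panel(alleles, positions=None, population="TEST", chromosome="1"):
    """Panel from a literal allele matrix; cM = Mb (1 cM/Mb map)."""
    alleles = np.asarray(alleles, dtype=np.int8)
    m = alleles.shape[1]
    if positions is None:
        positions = [100_000 * (i + 1) for i in range(m)]
    snps = [
        SnpMeta(
            rsid=f"rs{i + 1:04d}",
            chromosome=chromosome,
            position_bp=int(p),
            allele0="A",
            allele1="G",
            cm_position=p / 1e6,
        )
        for i, p in enumerate(positions)
    ]
    return HaplotypePanel(population, snps, alleles)


def random_panel(rng, n_chrom=None, n_snps=None):
    """Small random panel with irregular SNP spacing (missing-free)."""
    n = n_chrom or int(rng.integers(2, 9)) * 2
    m = n_snps or int(rng.integers(3, 13))
    alleles = rng.integers(0, 2, size=(n, m)).astype(np.int8)
    positions = np.sort(
        rng.choice(np.arange(1, 10_000_000), size=m, replace=False)
    )
    return make_panel(alleles, positions)


@pytest.fixture
def toy_panel():
    """8 chromosomes x 6 SNPs; rows 0, 4 and 6 share one full haplotype."""
    return make_panel(
        [
            [0, 1, 1, 0, 1, 0],
            [0, 1, 1, 0, 1, 1],
            [1, 1, 1, 0, 0, 1],
            [1, 0, 0, 1, 0, 1],
            [0, 1, 1, 0, 1, 0],
            [1, 0, 0, 1, 1, 0],
            [0, 1, 1, 0, 1, 0],
            [1, 0, 1, 1, 0, 1],
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20140)
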