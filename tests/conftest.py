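import numpy as np
import pytest

from ibdcoal.panel_io import DemographicModel, GeneticMap, HaplotypePanel


def make_random_panel(rng, n_hap, n_sites, length_cm=2.0, chrom="1"):
    """Random polymorphic panel with uniformly spaced sites."""
    alleles = (rng.random((n_hap, n_sites)) < rng.uniform(0.1, 0.9, n_sites)).astype(np.uint8)
    # force every column polymorphic
    for j in range(n_sites):
        col = alleles[:, j]
        if col.all():
            col[rng.integers(n_hap)] = 0
        elif not col.any():
            col[rng.integers(n_hap)] = 1
    if n_hap % 2:
        raise ValueError("n_hap must be even")
    phys = np.arange(1, n_sites + 1) * 1000
    gen = np.linspace(0.0, length_cm, n_sites)
    ids = [f"i{k}" for k in range(n_hap // 2)]
    return HaplotypePanel(ids, chrom, phys, gen, alleles)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def const_model():
    return DemographicModel([(0.0, 5000.0)])


@pytest.fixture
def two_epoch_model():
    return DemographicModel([(0.0, 5000.0), (300.0, 10000.0)])


@pytest.fixture
def toy_panel(rng):
    return make_random_panel(rng, 8, 120, length_cm=3.0)


@pytest.fixture
def uniform_map():
    return GeneticMap.uniform(10.0)


def write_toy_vcf(path, phased=True, genotypes=None):
    """2-sample, 3-site biallelic VCF."""
    sep = "|" if phased else "/"
    if genotypes is None:
        genotypes = [
            [(0, 1), (1, 0)],
            [(1, 1), (0, 0)],
            [(0, 0), (0, 1)],
        ]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n")
        for i, row in enumerate(genotypes):
            gts = "\t".join(f"{a}{sep}{b}" for a, b in row)
            fh.write(f"1\t{100 * (i + 1)}\tv{i}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
    return path
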