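import numpy as np
import pandas as pd
import pytest

from spikegwas.genotype_io import GenotypeMatrix
from spikegwas.simulate import SimConfig, make_truth, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_accessions=80, n_chroms=2, snps_per_chrom=120, seed=11)


@pytest.fixture(scope="session")
def small_gm(small_cfg):
    return simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def qtl_dataset():
    """Simulated panel with two strong planted QTLs and phenotypes."""
    cfg = SimConfig(n_accessions=150, n_chroms=2, snps_per_chrom=200,
                    n_qtl=2, qtl_h2=0.10, seed=13)
    gm = simulate_genotypes(cfg)
    truth = make_truth(gm, cfg)
    pheno = simulate_phenotypes(gm, truth, cfg)
    return cfg, gm, truth, pheno


def make_gm(dosages, positions=None, chrom="chr1", accessions=None):
    """Hand-build a GenotypeMatrix from a dosage array (-1 = missing)."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    if accessions is None:
        accessions = [f"a{i}" for i in range(n)]
    chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
    variants = pd.DataFrame({
        "id": [f"{c}_{p}" for c, p in zip(chroms, positions)],
        "chrom": chroms,
        "pos": positions,
        "ref": "A",
        "alt": "T",
    })
    return GenotypeMatrix(d, accessions, variants)


@pytest.fixture
def tiny_vcf(tmp_path):
    """Handcrafted VCF: 3 samples, 4 biallelic SNPs (one phased, one with
    missing calls) plus one multiallelic record that must be skipped."""
    text = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\tv1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\tv2\tG\tC\t.\t.\t.\tGT\t1|1\t1|0\t0|0
chr1\t300\tv3\tT\tA\t.\t.\t.\tGT\t./.\t0/0\t0/1
chr1\t350\tvmulti\tA\tT,G\t.\t.\t.\tGT\t0/1\t0/2\t1/2
chr1\t400\tv4\tC\tG\t.\t.\t.\tGT\t1/1\t1/1\t1/1
"""
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path
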