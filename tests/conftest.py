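import numpy as np
import pytest

VCF_TOY = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\tv1\tA\tC\t.\t.\t.\tGT\t0/0\t0/1\t1/1
1\t150\tv2\tA\tG\t.\t.\t.\tGT\t./.\t0/0\t1/1
1\t200\tv3\tT\tC\t.\t.\t.\tGT\t1/1\t1/1\t0/1
1\t250\tv4\tT\tA,G\t.\t.\t.\tGT\t0/1\t0/0\t0/2
1\t300\tv5\tG\tA\t.\t.\t.\tGT\t0/0\t0/0\t0/0
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_TOY)
    return path


@pytest.fixture
def toy_pheno(tmp_path):
    path = tmp_path / "pheno.tsv"
    path.write_text(
        "id\tSBP\tDBP\tMED\tAGE\tSEX\n"
        "S1\t142\t85\t0\t51\t1\n"
        "S2\t139\t89\t0\t\t0\n"
        "S3\t120\t80\t1\t33\t0\n"
    )
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def draw_polymorphic_gene(rng, n, p, maf_beta=(0.2, 5.0)):
    """Dosage block with every column polymorphic (for test genes)."""
    maf = np.minimum(rng.beta(*maf_beta, size=p), 0.5)
    X = rng.binomial(2, maf, size=(n, p)).astype(float)
    bad = np.ptp(X, axis=0) == 0
    while bad.any():
        k = int(bad.sum())
        maf[bad] = np.minimum(rng.beta(*maf_beta, size=k), 0.5)
        X[:, bad] = rng.binomial(2, maf[bad], size=(n, k))
        bad = np.ptp(X, axis=0) == 0
    return X, maf
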