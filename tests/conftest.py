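import numpy as np
import pytest

VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=17>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    """3 samples x 2 biallelic SNVs, plus one triallelic record to skip."""
    path = tmp_path / "tiny.vcf"
    path.write_text(
        VCF_HEADER
        + "17\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        + "17\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/1\t0/1\t./.\n"
        + "17\t300\trs3\tG\tA,T\t.\t.\t.\tGT\t0/0\t0/1\t0/2\n"
    )
    return str(path)


@pytest.fixture
def rng():
    return np.random.default_rng(20240607)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across read-only tests."""
    from haplobiva.synthetic_data import CohortSpec, generate_study

    return generate_study(CohortSpec(seed=11))
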