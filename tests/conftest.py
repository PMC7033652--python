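import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=100001>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0|0\t0|1\t1|1
1\t20000\t.\tG\tT\t.\tPASS\t.\tGT\t0|1\t0|0\t0|0
1\t50000\t.\tT\tA\t.\tPASS\t.\tGT\t1|1\t1|0\t0|0
1\t50010\t.\tC\tG,A\t.\tPASS\t.\tGT\t0|0\t0|1\t0|2
1\t50020\t.\tC\tCAT\t.\tPASS\t.\tGT\t0|0\t0|1\t0|0
"""

TOY_VCF_UNPHASED = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=100001>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\t.\tG\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return str(path)


@pytest.fixture
def toy_vcf_unphased(tmp_path):
    path = tmp_path / "toy_unphased.vcf"
    path.write_text(TOY_VCF_UNPHASED)
    return str(path)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
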