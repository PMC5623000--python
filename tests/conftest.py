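import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from genofp import CohortModel, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_model():
    """Desk-scale cohort pool shared by tests that only need *a* genome."""
    return CohortModel.create(n_chroms=4, n_loci=8000, seed=11)


@pytest.fixture(scope="session")
def small_genome(small_model):
    genomes, _ = simulate_cohort(small_model, 1, seed=5)
    return genomes[0]


MULTISAMPLE_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##contig=<ID=chr2,length=1000000>
##contig=<ID=chr3,length=1000000>
##contig=<ID=chrX,length=1000000>
##FILTER=<ID=q10,Description="low quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA1\tNA2
chr1\t100\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\t0/0
chr1\t120\t.\tGTT\tG\t.\tPASS\t.\tGT\t0/1\t0/1
chr1\t150\t.\tT\tC\t.\tq10\t.\tGT\t1/1\t./.
chr1\t150\t.\tT\tG\t.\tPASS\t.\tGT\t0/1\t0/1
chr1\t200\t.\tA\tG,T\t.\tPASS\t.\tGT\t1/2\t0/1
chr1\t250\t.\tC\tT\t.\tPASS\t.\tGT\t1|0\t0|0
chr2\t300\t.\tG\tC\t.\tPASS\t.\tGT\t0/1\t1/1
chrX\t400\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\t1/1
chr3\t500\t.\tA\tT\t.\tPASS\t.\tGT\t./.\t0/1
"""


@pytest.fixture()
def multisample_vcf(tmp_path):
    path = tmp_path / "cohort.vcf"
    path.write_text(MULTISAMPLE_VCF)
    return path
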