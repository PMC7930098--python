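import numpy as np
import pytest

from mixqtl import GeneCounts, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def null_dataset():
    """One simulated gene with no genetic effect (n=500, theta=5e-5)."""
    return simulate_dataset(SimConfig(seed=11, afc=1.0))


@pytest.fixture(scope="session")
def signal_dataset():
    """One simulated gene with a strong single causal variant."""
    return simulate_dataset(SimConfig(seed=12, afc=2.0))


@pytest.fixture(scope="session")
def multi_variant_dataset():
    """A fine-mapping-sized gene: 100 cis-variants, one causal, h2=0.4."""
    return simulate_dataset(SimConfig(seed=13, h2=0.4, n_causal=1,
                                      n_cis_variants=100))


@pytest.fixture
def tiny_counts():
    return GeneCounts(
        total=np.array([200, 0, 2_000_000, 150]),
        asc1=np.array([50, 100, 1200, 40]),
        asc2=np.array([50, 50, 300, 35]),
        libsize=np.array([1_000_000, 1_000_000, 1_000_000, 1_000_000]),
        samples=["A", "B", "C", "D"],
    )


VCF_BODY = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t999999\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0
1\t1000000\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t0|0\t1|0
1\t1500000\trs3\tG\tA\t.\tPASS\t.\tGT\t1|0\t.|.\t0|1
1\t3000001\trs4\tT\tC,G\t.\tPASS\t.\tGT\t0|1\t0|0\t0|2
"""


@pytest.fixture
def small_vcf(tmp_path):
    path = tmp_path / "small.vcf"
    path.write_text(VCF_BODY)
    return str(path)
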