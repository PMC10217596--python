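import pytest

from lncsnp import datasets
from lncsnp.synthetic import TwoLocusSpec, gen_two_locus


@pytest.fixture(scope="session")
def published_counts():
    """Published case-control genotype counts for the four genotyped SNPs."""
    return {snp: datasets.counts(snp) for snp in datasets.SNP_DEFS}


@pytest.fixture(scope="session")
def two_locus_cohort():
    """10^4 individuals drawn from the published haplotype frequency vector."""
    spec = TwoLocusSpec(
        snp_a=datasets.SNP_DEFS["rs3803662"],
        snp_b=datasets.SNP_DEFS["rs4784227"],
        haplotype_freqs={"case": datasets.HAPLOTYPE_FREQS},
        n_per_group={"case": 10_000},
        seed=20230425,
    )
    return gen_two_locus(spec)
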