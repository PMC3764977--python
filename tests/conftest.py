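import numpy as np
import pytest

from ibdcheck.genotype_data import GenotypeTable, SnpInfo, SubjectInfo


def make_table(genotypes, n_ref=None, chrom=1, spacing_bp=1_000_000, cm=True):
    """GenotypeTable from a genotype matrix; first n_ref subjects are the
    reference pool (default: all)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sub, n_snp = g.shape
    n_ref = n_sub if n_ref is None else n_ref
    snps = [
        SnpInfo(
            f"snp{m + 1}",
            chrom,
            1 + m * spacing_bp,
            genetic_pos=(1 + m * spacing_bp) / 1e6 if cm else None,
        )
        for m in range(n_snp)
    ]
    subjects = [SubjectInfo(f"sub{i + 1}", is_reference=i < n_ref) for i in range(n_sub)]
    return GenotypeTable(g, snps, subjects)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_table():
    """3 subjects x 4 SNPs, complete data, all reference."""
    return make_table(
        [
            [2, 1, 0, 1],
            [1, 1, 1, 0],
            [0, 2, 1, 1],
        ]
    )
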