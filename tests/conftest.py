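import pytest

from oriterscan.synthetic_data import (
    default_dup_segment,
    desk_scale_chromosome,
    full_scale_chromosome,
    gen_gene_annotations,
)


@pytest.fixture(scope="session")
def full_chrom():
    return full_scale_chromosome()


@pytest.fixture(scope="session")
def desk_chrom():
    return desk_scale_chromosome()


@pytest.fixture(scope="session")
def desk_genes(desk_chrom):
    return gen_gene_annotations(desk_chrom, 460)


@pytest.fixture(scope="session")
def desk_dup(desk_chrom):
    return default_dup_segment(desk_chrom)


@pytest.fixture(scope="session")
def full_dup(full_chrom):
    return default_dup_segment(full_chrom)
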