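import numpy as np
import pytest

from pausepipe.regions import GeneModel, GenomicInterval
from pausepipe.simulate import SyntheticConfig, simulate_annotation


@pytest.fixture
def small_config():
    """Toy scenario small enough for exhaustive checks."""
    return SyntheticConfig(
        seed=11,
        n_genes=20,
        n_enhancers=6,
        n_decoy_peaks=3,
        atac_fragments_per_sample=8000,
        nb_n_regions=300,
    )


@pytest.fixture
def toy_genes(small_config):
    genes, _ = simulate_annotation(small_config)
    return genes


@pytest.fixture
def plus_gene():
    return GeneModel(
        gene_id="gplus", chrom="chr1", strand="+", tss=10_000, tes=13_000,
        biotype="protein_coding",
        exons=[GenomicInterval("chr1", 10_000, 13_000, "+")],
        canonical_transcript_id="tplus",
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        gene_id="gminus", chrom="chr1", strand="-", tss=33_000, tes=30_000,
        biotype="protein_coding",
        exons=[GenomicInterval("chr1", 30_000, 33_000, "-")],
        canonical_transcript_id="tminus",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
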