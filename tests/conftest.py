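import numpy as np
import pandas as pd
import pytest

from regland.types import AlleleCountTable, GeneModel, PhasedHaplotypeSet


def make_haps(hap_matrix, positions=None, chrom="1", **kwargs):
    """Small PhasedHaplotypeSet from a (n_samples, 2, n_sites) list/array."""
    hap = np.asarray(hap_matrix, dtype=np.int8)
    n_samples, _, n_sites = hap.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    return PhasedHaplotypeSet(
        sample_ids=[f"S{i}" for i in range(n_samples)],
        chrom=chrom,
        positions=np.asarray(positions),
        alleles=[("A", "G")] * n_sites,
        haplotypes=hap,
        **kwargs,
    )


def make_counts(rows):
    """AlleleCountTable from (sample_id, site, ref, alt, bias) tuples."""
    return AlleleCountTable(
        pd.DataFrame(rows, columns=list(AlleleCountTable.COLUMNS))
    )


@pytest.fixture
def two_sample_haps():
    # one site: S0 het 0|1, S1 hom-alt 1|1 -> alt freq 0.75
    return make_haps([[[0], [1]], [[1], [1]]])


@pytest.fixture
def single_exon_gene():
    return GeneModel(gene_id="G0", strand="+", tss=1000,
                     exons=[(1000, 1500)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
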