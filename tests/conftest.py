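import numpy as np
import pytest

from rootqtl import synthetic_data as sd


@pytest.fixture(scope="session")
def small_genome():
    return sd.make_genome(n_chrom=2, genes_per_chrom=30, gene_len=300, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_genome):
    return sd.make_il_panel(small_genome, n_ils=6, overlap_frac=0.25,
                            n_subils=2, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_genome, small_panel):
    rng = np.random.default_rng(11)
    dispersions = {g: float(np.exp(rng.normal(np.log(0.01), 0.3)))
                   for g in small_genome.gene_ids}
    il = small_panel[1]
    causal = next(g for g in small_genome.genes if il.contains_gene(g))
    return sd.SimTruth(cis_effects={causal.gene_id: 1.5},
                       trait_effects={causal.gene_id: 8.0},
                       causal_gene=causal.gene_id,
                       dispersions=dispersions, seed=11)
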