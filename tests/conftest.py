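import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from mafdiverge import SimConfig, simulate_bundle
from mafdiverge.ld import GenotypePanel

TINY = SimConfig(n_samples_a=60, n_samples_b=60, n_snps=300, block_len=10,
                 n_founder_haplotypes=40, fst=0.02, n_planted=6,
                 planted_delta_min=0.15, planted_pval_max=1e-5,
                 genome_len=150_000, n_genes=12, n_pathways=6, n_motifs=4,
                 seed=11)


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """A small synthetic bundle written to disk, shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(TINY, out)


@pytest.fixture
def make_panel():
    """Factory for small hand-specified genotype panels."""
    def _make(columns: dict[str, list[float]], chrom="1", positions=None):
        ids = list(columns)
        n = len(ids)
        positions = positions or [1000 * (i + 1) for i in range(n)]
        geno = np.array([columns[s] for s in ids], dtype=float).T
        variants = pd.DataFrame({"snp_id": ids, "chrom": chrom,
                                 "pos": positions, "ref": "A", "alt": "G"})
        return GenotypePanel(genotypes=geno, variants=variants)
    return _make
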