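import numpy as np
import pytest

import orphanforge as of


@pytest.fixture(scope="session")
def mixed_scenario():
    """One synthetic contig with genes of every class plus related resources."""
    genome, models, ledger = of.synth_genome_with_genes(
        contig_len=120_000, seed=11,
        classes={"conserved": 5, "orphan_unknown": 3, "orphan_dup": 1,
                 "orphan_te": 1, "orphan_overlap": 1, "orphan_denovo": 2},
    )
    proteins = [of.ProteinRecord(m.gene_id, m.protein_sequence(genome))
                for m in models]
    return genome, models, ledger, proteins


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
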