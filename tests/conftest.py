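import numpy as np
import pytest

from orgws.synthetic_data import GenomeSpec, generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A small synthetic genome shared by fast tests: 6 genes incl. one
    pseudogene, one edge partial and a tandem pair."""
    spec = GenomeSpec(n_scaffolds=2, scaffold_length=60_000, n_genes=6,
                      n_pseudogenes=1, n_partials=1,
                      tandem_cluster_spec=[(2, 2000)], seed=5)
    scaffolds, truth, queries, gff = generate_genome(spec)
    return {"spec": spec, "scaffolds": scaffolds, "truth": truth,
            "queries": queries, "gff": gff}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
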