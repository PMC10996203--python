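import numpy as np
import pytest

from structrip.synthetic_data import (
    GenomeSpec, LibrarySim, build_reference, default_truth, simulate_libraries,
)


@pytest.fixture(scope="session")
def compact_spec():
    return GenomeSpec(
        n_coding_genes=10, n_snorna_haca=20, n_snorna_cd=17,
        n_scarna=3, n_mirna=3, seed=5,
    )


@pytest.fixture(scope="session")
def bundle(compact_spec):
    return build_reference(compact_spec)


@pytest.fixture(scope="session")
def truth(bundle):
    return default_truth(bundle, rng=np.random.default_rng(12))


@pytest.fixture(scope="session")
def sim_result(bundle, truth):
    sim = LibrarySim(n_fragments=8000, n_replicates=2, seed=7)
    return simulate_libraries(truth, sim, bundle)
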