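import numpy as np
import pandas as pd
import pytest

from radpop import GenotypeMatrix, locus_stats


def make_matrix(calls, depths=None, scaffold="scaf1", positions=None, ids=None):
    """Build a small GenotypeMatrix from a nested list (rows = individuals)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_loci = calls.shape
    if positions is None:
        positions = 100 * (np.arange(n_loci) + 1)
    if np.isscalar(scaffold) or isinstance(scaffold, str):
        scaffold = [scaffold] * n_loci
    loci = pd.DataFrame(
        {"scaffold": scaffold, "position": positions, "ref": "A", "alt": "G"}
    )
    ids = ids or [f"ind{i}" for i in range(n_ind)]
    G = GenotypeMatrix(ids, loci, calls, None if depths is None else np.asarray(depths))
    return locus_stats(G)


@pytest.fixture
def matrix_factory():
    return make_matrix
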