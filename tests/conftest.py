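import warnings

import numpy as np
import pytest

from nacmap import (
    PreprocessSpec,
    SyntheticConfig,
    generate_cohort,
    subject_map,
)


@pytest.fixture(scope="session")
def star_adjacency():
    """K_{1,3}: node 0 is the center."""
    a = np.zeros((4, 4), dtype=int)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return a


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale null cohort (no planted hubs), two groups of six."""
    cfg = SyntheticConfig(
        n_per_group={"male": 6, "female": 6}, n_nodes=84, n_noise_nodes=12, seed=11
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_maps(small_cohort):
    """Per-subject centrality maps for the small cohort at Z > 2.58."""
    _, cohort = small_cohort
    spec = PreprocessSpec()
    maps, labels = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in cohort.subjects:
            m, _ = subject_map(s, spec, 2.58)
            maps.append(m)
            labels.append(s.group_label)
    return cohort, maps, np.asarray(labels)


def random_connected_adjacency(rng, n, p=0.3):
    """Random symmetric adjacency, re-drawn until connected."""
    from scipy import sparse
    from scipy.sparse.csgraph import connected_components

    while True:
        a = (rng.random((n, n)) < p).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        ncomp, _ = connected_components(sparse.csr_matrix(a), directed=False)
        if ncomp == 1:
            return a
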