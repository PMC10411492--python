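import numpy as np
import pytest

import xgrove as xg
from xgrove import trees as T


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def quartet():
    return T.read_newick("((A:0.1,B:0.2)90:0.15,C:0.3,D:0.05);")


@pytest.fixture
def gtr_model():
    return xg.GTRModel(freqs=(0.3, 0.2, 0.3, 0.2),
                       rates=(1.5, 3.0, 0.8, 1.2, 4.0, 1.0), alpha=0.7)


@pytest.fixture(scope="session")
def small_locus_set():
    """A reduced fast-X locus set shared by read-only tests."""
    cfg = xg.preset("faster_x_demo", n_autosomal_loci=25, n_x_loci=6,
                    length_range=(300, 300), seed=11)
    rng = np.random.default_rng(cfg.seed)
    st = xg.simulate_species_tree(cfg, rng=rng)
    recs, truth = xg.simulate_locus_set(cfg, species_tree=st, rng=rng)
    return cfg, st, recs, truth
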