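import numpy as np
import pytest

from smorf.synthetic_data import SimulationConfig, simulate_locus_set


@pytest.fixture(scope="session")
def bundle():
    """One mid-sized synthetic bundle shared by the module tests."""
    cfg = SimulationConfig(seed=11, n_annotated=25, n_novel=10,
                           n_neutral_ncrna=25, n_neutral_linc=5,
                           n_pseudogene=5)
    return simulate_locus_set(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(202)
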