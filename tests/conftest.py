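import numpy as np
import pytest

import promptdiff as pd
from promptdiff.training import _toy_schedule


@pytest.fixture(scope="session")
def vocab():
    return pd.AtomVocabulary()


@pytest.fixture(scope="session")
def toy_schedule():
    return _toy_schedule(100)


@pytest.fixture(scope="session")
def hbond_complex():
    """Toy complex with one planted hydrogen bond (3-atom ligand)."""
    return pd.make_toy_complex(pd.ToyComplexSpec(planted=((0, "hydrogen"),)))


@pytest.fixture(scope="session")
def small_denoiser(hbond_complex, vocab):
    graph, _ = hbond_complex
    cfg = pd.DenoiserConfig(n_blocks=2, hidden=32, nheads=2, dist_dim=16,
                            n_rbf=16)
    return pd.Denoiser(cfg, vocab, graph.h_P().shape[1], seed=7)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
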