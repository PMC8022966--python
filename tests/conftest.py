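import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import bdtsel as b

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_fixture():
    """Deterministic 12-line, 2-trait synthetic population."""
    return b.make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_bundle(tiny_fixture):
    phenotypes, G, _, _ = tiny_fixture
    return b.DataBundle(phenotypes=phenotypes, relationship=G)


@pytest.fixture(scope="session")
def small_bundle():
    """n=50, t=2 population with known variance components, for sampler checks."""
    rng_seed = 5
    X = b.simulate_markers(50, 200, seed=rng_seed)
    G = b.compute_grm(b.center_scale_markers(X))
    sigma_g = np.array([[1.0, 0.4], [0.4, 0.8]])
    r_diag = np.array([1.0, 1.5])
    y, truth = b.simulate_population(G.values, np.array([5.0, -2.0]), sigma_g, r_diag, seed=7)
    ids = [f"L{i:02d}" for i in range(50)]
    ph = pd.DataFrame(y, index=pd.Index(ids, name="line"), columns=["a", "b"])
    bundle = b.DataBundle(phenotypes=ph, relationship=G)
    return bundle, truth


@pytest.fixture(scope="session")
def small_chain(small_bundle):
    """Short (but real) posterior chain on the 50-line population."""
    bundle, _ = small_bundle
    return b.fit_mtm(bundle, b.MCMCConfig(n_burn=300, n_kept=200, seed=17))
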