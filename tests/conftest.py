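import numpy as np
import pytest

import midparc as mp


@pytest.fixture(scope="session")
def phantom64():
    """Default 64^3 phantom (no crossing, no angular noise)."""
    return mp.build_phantom(mp.default_phantom_spec(rng_seed=0))


@pytest.fixture(scope="session")
def parcellated_R(phantom64):
    """One two-step parcellation of the right side at default parameters."""
    params = mp.TrackingParams(n_streamlines=5000, rng_seed=42)
    st, mb, tg1, tg2 = mp.two_step_parcellate(
        phantom64.seed_masks["striatum_R"], phantom64.cortical_targets["R"],
        phantom64.seed_masks["midbrain_R"], phantom64.field, params,
        return_tractograms=True)
    return st, mb, tg1, tg2


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
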