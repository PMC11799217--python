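import numpy as np
import pytest

from cocktailtrf import RegressorSet
from cocktailtrf.scene import SceneSpec, gen_scene, gen_true_trf

#: reduced lag axis covering all kernel components; keeps design matrices small
SHORT_LAGS = (-0.1, 0.45)


@pytest.fixture(scope="session")
def noiseless_scene():
    """Small noiseless two-stream scene with lateralized mixing."""
    spec = SceneSpec(n_trials=8, noise_snr_db=None, seed=3, lag_range=SHORT_LAGS)
    trf_t = gen_true_trf(attention=True, lag_range=SHORT_LAGS)
    trf_m = gen_true_trf(attention=False, lag_range=SHORT_LAGS)
    rec, events, truth = gen_scene(spec, trf_t, trf_m)
    return spec, rec, events, truth


@pytest.fixture(scope="session")
def noiseless_regs(noiseless_scene):
    _, rec, _, truth = noiseless_scene
    return RegressorSet(dict(truth.regressors), rec.rate)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
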