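import numpy as np
import pytest

from respigate import synthetic


@pytest.fixture
def steady_breathing():
    """Jitter-free 15 bpm, 40:60 inspiration:expiration, 90 s latent trace."""
    params = synthetic.BreathingParams(rate_bpm=15.0, rate_jitter=0.0,
                                       insp_fraction=0.4, duration_s=90.0,
                                       seed=1)
    return synthetic.gen_breathing_waveform(params)


@pytest.fixture
def modality_pair(steady_breathing):
    """Noise-free camera/navigator observation of the steady trace."""
    return synthetic.gen_modality_pair(steady_breathing, seed=1)


@pytest.fixture
def clean_phantom():
    """Noise-free, blur-free phantom with edge width exactly 2 voxels."""
    spec = synthetic.PhantomSpec(noise_sd=0.0, motion_blur_sd=0.0,
                                 edge_width_w=2.0, seed=0)
    return synthetic.gen_phantom_volume(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
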