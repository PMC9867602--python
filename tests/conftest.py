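import numpy as np
import pytest

import mesophot as mp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng):
    """8 x 8 x 400 random stack around a positive baseline, full mask."""
    frames = 100.0 + rng.standard_normal((8, 8, 400))
    return mp.WidefieldStack(frames, fs=40.0)


def make_scene(**overrides) -> mp.SceneConfig:
    """A small, fast spontaneous scene; override any field."""
    defaults = dict(
        height=16,
        width=16,
        duration=120.0,
        motif_specs=[mp.MotifSpec("ap_wave", length=20, rate=0.2)],
        photometry_couplings=[mp.PhotometryCoupling(0, delay_ms=300.0)],
        seed=7,
    )
    defaults.update(overrides)
    return mp.SceneConfig(**defaults)


@pytest.fixture
def spontaneous_session():
    cfg = make_scene()
    return cfg, mp.generate_spontaneous_session(cfg)
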