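import numpy as np
import pytest

from arcpipe import synthetic
from arcpipe.photometry import PhotometrySession


@pytest.fixture
def clean_session() -> PhotometrySession:
    """Noise-free session with shared motion and identical bleach: the 405
    channel predicts the 465 channel exactly through an affine map."""
    cfg = synthetic.PhotometryGenConfig(
        duration=120.0, noise_sd=0.0, motion_sd=0.02, motion_coupling_405=1.0,
        transient_times=(), seed=7,
    )
    session, _ = synthetic.simulate_photometry(cfg)
    return session


@pytest.fixture
def small_counts_cfg() -> synthetic.CountsGenConfig:
    """Planted-population count matrix small enough for per-test use."""
    return synthetic.CountsGenConfig(
        n_cells={"Agrp_Npy": 120, "Pomc": 60, "Bnc2_Lepr": 40, "Nr5a1": 50,
                 "Other": 130},
        seed=11,
    )


@pytest.fixture
def small_counts(small_counts_cfg):
    return synthetic.simulate_counts(small_counts_cfg)


def constant_trace(value: float, n: int = 2000, fs: float = 100.0):
    from arcpipe.photometry import DffTrace

    t = np.arange(n) / fs
    return DffTrace(time=t, dff=np.full(n, value))
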