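import numpy as np
import pytest

from songpeth import synth
from songpeth.segmentation import SegmentationConfig, Spectrogram


@pytest.fixture(scope="session")
def small_truth():
    """Event schedule for a 600 s session with 20 SEs (no audio)."""
    cfg = synth.SynthSessionConfig(duration_s=600.0, n_se=20, seed=3, audio_fs=1000.0)
    return synth.synth_session_truth(cfg)


@pytest.fixture(scope="session")
def short_audio_session():
    """90 s audio session at full 250 kHz with its ground truth."""
    cfg = synth.SynthSessionConfig(duration_s=90.0, n_se=4, seed=7)
    wave, truth = synth.synth_usv_audio(cfg)
    return cfg, wave, truth


def make_ridge_spectrogram(ridges, n_time=400, n_freq=60, dt=0.001, f0=20_000.0,
                           df=1_000.0, seed=0, signal=1e4):
    """Synthetic spectrogram: exponential noise floor + high-power ridges.

    ``ridges`` is a list of (t0_bin, t1_bin, row_lo, row_hi) blocks painted at
    ``signal`` power.  Time axis has exact ``dt`` spacing so duration/gap
    boundary rules evaluate without discretization surprises.
    """
    rng = np.random.default_rng(seed)
    power = rng.exponential(1.0, size=(n_freq, n_time))
    for t0, t1, r0, r1 in ridges:
        power[r0:r1, t0:t1] = signal
    times = np.arange(n_time) * dt
    freqs = f0 + np.arange(n_freq) * df
    return Spectrogram(power=power, times=times, freqs=freqs)


@pytest.fixture
def boundary_cfg():
    """Segmentation config whose STFT grid matches the 1 ms fixture grid."""
    return SegmentationConfig()
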