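import numpy as np
import pytest

from thetamaze.simdata import (
    MultiSiteRecording,
    PoolGeometry,
    SimConfig,
    make_theta_oscillator,
    one_over_f_noise,
)

FS = 1024.0


@pytest.fixture
def pool() -> PoolGeometry:
    return PoolGeometry()


@pytest.fixture
def small_config() -> SimConfig:
    """A scaled-down cohort (low fs, few subjects/days) for fast pipeline tests."""
    return SimConfig(
        fs=256.0,
        n_subjects={"CTR": 3, "EXP": 3},
        days=3,
        trials_per_day=2,
        peak_schedule={"CTR": [7.0, 7.5, 8.0], "EXP": [7.0, 7.0, 7.0]},
        bias_schedule={"CTR": [0.1, 0.3, 0.6], "EXP": [0.1, 0.1, 0.1]},
        seed=11,
    )


def make_recording(
    samples_per_channel, fs: float = FS, condition: str = "search", **meta
) -> MultiSiteRecording:
    """Wrap a 1-D signal (copied to all 4 channels) or an (n, 4) array."""
    arr = np.asarray(samples_per_channel, dtype=float)
    if arr.ndim == 1:
        arr = np.tile(arr[:, None], (1, 4))
    m = {"condition": condition, "subject": "T01", "group": "CTR", "day": 1, "trial": 1}
    m.update(meta)
    return MultiSiteRecording(samples=arr, fs=fs, meta=m)


def tone(freq: float, duration: float, fs: float = FS, amp: float = 1.0, phase: float = 0.0):
    t = np.arange(int(round(duration * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture
def noisy_theta():
    """60 s theta oscillator at 7.5 Hz over 1/f background at band SNR 2."""

    def _make(seed: int, f0: float = 7.5, snr: float = 2.0, duration: float = 60.0):
        from thetamaze.simdata import SimConfig, _bg_band_fraction

        osc = make_theta_oscillator(f0, 0.5, duration, FS, seed=seed)
        phi = _bg_band_fraction(SimConfig())
        bg = one_over_f_noise(duration, FS, seed=seed + 10_000, variance=1.0 / (snr * phi))
        return osc + bg

    return _make
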