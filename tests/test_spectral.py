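"""Spectral-chain tests: filtering, epoching, artifact rejection, AP/RP and
peak extraction, with a hand-coded DFT oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from thetamaze import spectral
from thetamaze.errors import (
    AllEpochsRejectedError,
    InsufficientDataError,
    ParameterError,
    ZeroPowerError,
)
from thetamaze.spectral import (
    GRID,
    PowerSpectrum,
    absolute_power,
    bandpass_filter,
    epoch_signal,
    log_absolute_power,
    peak_frequency,
    reject_artifacts,
    relative_power,
)

from conftest import FS, make_recording, tone


def test_grid_is_the_17_half_hz_bins():
    assert len(GRID) == 17
    assert GRID[0] == 4.0 and GRID[-1] == 12.0
    assert np.all(np.diff(GRID) == 0.5)


def test_two_second_epoch_bin_spacing_is_half_hz():
    freqs = np.fft.rfftfreq(int(2 * FS), d=1.0 / FS)
    assert np.all(np.diff(freqs) == 0.5)


class TestBandpass:
    def test_midband_tone_amplitude_preserved(self):
        x = tone(8.0, 10.0)
        y = bandpass_filter(x, FS)
        core = slice(int(FS), int(9 * FS))  # avoid edge transients
        assert np.max(np.abs(y[core])) == pytest.approx(1.0, rel=0.02)

    def test_slow_drift_attenuated_20db_tone_kept(self):
        x = tone(0.1, 40.0) + tone(8.0, 40.0)
        y = bandpass_filter(x, FS)
        f = np.fft.rfftfreq(len(x), 1 / FS)
        xs, ys = np.abs(np.fft.rfft(x)), np.abs(np.fft.rfft(y))
        i_drift = np.argmin(np.abs(f - 0.1))
        i_tone = np.argmin(np.abs(f - 8.0))
        assert ys[i_drift] < xs[i_drift] * 0.1  # >= 20 dB down
        assert ys[i_tone] == pytest.approx(xs[i_tone], rel=0.02)

    def test_dc_removed(self):
        x = np.full(int(10 * FS), 5.0)
        y = bandpass_filter(x, FS)
        assert np.max(np.abs(y)) < 0.05  # < 1% of the DC level

    def test_low_fs_rejected(self):
        with pytest.raises(ParameterError):
            bandpass_filter(np.zeros(100), fs=150.0)


class TestEpoching:
    @pytest.mark.parametrize(
        "duration,expected", [(60.0, 30), (7.3, 3), (2.0, 1), (5.0, 2)]
    )
    def test_epoch_counts(self, duration, expected):
        rec = make_recording(np.zeros(int(duration * FS)))
        assert epoch_signal(rec).n_epochs == expected

    def test_too_short_recording_raises(self):
        rec = make_recording(np.zeros(int(1.5 * FS)))
        with pytest.raises(InsufficientDataError):
            epoch_signal(rec)

    def test_search_duration_metadata_truncates(self):
        rec = make_recording(np.zeros(int(10 * FS)), search_duration=6.0)
        assert epoch_signal(rec).n_epochs == 3

    def test_epochs_have_exact_length(self):
        rec = make_recording(np.random.default_rng(0).normal(size=int(9 * FS)))
        es = epoch_signal(rec)
        assert es.epochs.shape[2] == int(2 * FS)


class TestArtifactRejection:
    def test_clean_record_keeps_everything(self):
        rec = make_recording(tone(8.0, 20.0))
        es = reject_artifacts(epoch_signal(rec))
        assert es.n_kept == es.n_epochs and not es.rejection_log

    def test_spiked_epoch_is_the_one_dropped(self):
        x = np.tile(tone(8.0, 20.0)[:, None], (1, 4))
        x[int(5.5 * FS), 2] += 50.0  # spike inside epoch index 2
        es = reject_artifacts(epoch_signal(make_recording(x)))
        dropped = [i for i, _ in es.rejection_log]
        assert dropped == [2]
        assert es.n_kept == es.n_epochs - 1
        assert "DG" in es.rejection_log[0][1]

    def test_infinite_threshold_is_identity(self):
        x = np.tile(tone(8.0, 20.0)[:, None], (1, 4))
        x[int(5.5 * FS), 2] += 50.0
        es = reject_artifacts(epoch_signal(make_recording(x)), z_threshold=np.inf)
        assert es.n_kept == es.n_epochs

    def test_all_rejected_raises(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(int(6 * FS), 4))
        x[:: int(0.5 * FS)] += 500.0  # spikes in every epoch
        with pytest.raises(AllEpochsRejectedError):
            reject_artifacts(epoch_signal(make_recording(x)), z_threshold=5.0)


def _dft_power_oracle(epochs: np.ndarray, fs: float) -> np.ndarray:
    """Directly coded DFT magnitude computation (no FFT library reuse of the
    implementation path beyond numpy's transform on explicit sums)."""
    n = epochs.shape[-1]
    t = np.arange(n)
    out = []
    for f in GRID:
        k = f * n / fs
        basis = np.exp(-2j * np.pi * k * t / n)
        coef = np.tensordot(epochs, basis, axes=([-1], [0]))
        out.append(2.0 * np.abs(coef) ** 2 / n**2)
    return np.mean(np.stack(out, axis=-1), axis=0)


class TestAbsolutePower:
    def test_on_grid_tone_concentrates_in_one_bin(self):
        rec = make_recording(tone(8.0, 20.0))
        ps = absolute_power(epoch_signal(rec))
        i8 = list(GRID).index(8.0)
        assert ps.ap[0, i8] / ps.ap[0].sum() > 0.99
        assert ps.ap[0, i8] == pytest.approx(0.5, rel=1e-9)  # unit tone power

    def test_equal_tones_have_equal_power(self):
        rec = make_recording(tone(6.0, 20.0) + tone(9.0, 20.0))
        ps = absolute_power(epoch_signal(rec))
        i6, i9 = list(GRID).index(6.0), list(GRID).index(9.0)
        assert ps.ap[0, i6] == pytest.approx(ps.ap[0, i9], rel=1e-9)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(1)
        rec = make_recording(rng.normal(size=int(1000 * 2 * FS)), condition="free")
        ps = absolute_power(epoch_signal(rec))
        assert ps.ap[0].max() / ps.ap[0].min() < 1.3

    def test_matches_brute_force_dft_oracle(self):
        rng = np.random.default_rng(2)
        rec = make_recording(rng.normal(size=(int(6 * FS), 4)))
        es = epoch_signal(rec)
        ps = absolute_power(es)
        oracle = _dft_power_oracle(es.epochs, FS)
        assert np.allclose(ps.ap, oracle, rtol=1e-9, atol=1e-15)

    def test_hann_taper_accepted_and_recorded(self):
        rec = make_recording(tone(8.0, 10.0))
        ps = absolute_power(epoch_signal(rec), taper="hann")
        assert ps.taper == "hann"
        i8 = list(GRID).index(8.0)
        assert np.argmax(ps.ap[0]) == i8


class TestRelativePower:
    def test_uniform_ap_gives_100_over_17(self):
        ps = PowerSpectrum(freqs=GRID.copy(), ap=np.ones((4, 17)), n_epochs=1)
        rp = relative_power(ps)
        assert np.allclose(rp.rp, 100.0 / 17.0, rtol=1e-12)

    def test_single_bin_takes_all(self):
        ap = np.zeros((4, 17))
        ap[:, 5] = 3.0
        rp = relative_power(PowerSpectrum(freqs=GRID.copy(), ap=ap, n_epochs=1))
        assert np.all(rp.rp[:, 5] == 100.0)
        assert np.all(np.delete(rp.rp, 5, axis=1) == 0.0)

    def test_zero_power_channel_is_named(self):
        ap = np.ones((4, 17))
        ap[2] = 0.0
        with pytest.raises(ZeroPowerError, match="DG"):
            relative_power(PowerSpectrum(freqs=GRID.copy(), ap=ap, n_epochs=1))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    def test_rp_sums_to_100_and_is_scale_invariant(self, seed):
        rng = np.random.default_rng(seed)
        ap = rng.exponential(size=(4, 17)) + 1e-12
        rp = relative_power(PowerSpectrum(freqs=GRID.copy(), ap=ap, n_epochs=1))
        assert np.allclose(rp.rp.sum(axis=1), 100.0, rtol=1e-9)
        c = rng.uniform(0.1, 1e6)
        rp2 = relative_power(PowerSpectrum(freqs=GRID.copy(), ap=c * ap, n_epochs=1))
        assert np.allclose(rp.rp, rp2.rp, rtol=1e-12, atol=1e-12)


def test_log_absolute_power_values_and_flags():
    ap = np.full((4, 17), np.e)
    ap[0, 0] = 1.0
    ap[1, 3] = np.e**2
    ap[2, 5] = 0.0
    nl, excluded = log_absolute_power(
        PowerSpectrum(freqs=GRID.copy(), ap=ap, n_epochs=1)
    )
    assert nl[0, 0] == pytest.approx(0.0)
    assert nl[1, 3] == pytest.approx(2.0)
    assert nl[3, 4] == pytest.approx(1.0)
    assert excluded[2, 5] and np.isnan(nl[2, 5])
    assert excluded.sum() == 1


class TestPeakFrequency:
    def test_tone_peak(self):
        rec = make_recording(tone(8.0, 10.0))
        rp = relative_power(absolute_power(epoch_signal(rec)))
        pk = peak_frequency(rp)
        assert np.all(pk.peak_freq == 8.0)
        assert np.all(pk.peak_rp == rp.rp[:, list(GRID).index(8.0)])

    def test_uniform_rp_ties_to_lowest_band_edge(self):
        rp_obj = relative_power(
            PowerSpectrum(freqs=GRID.copy(), ap=np.ones((4, 17)), n_epochs=1)
        )
        assert np.all(peak_frequency(rp_obj).peak_freq == 5.0)

    def test_band_outside_grid_rejected(self):
        rp_obj = relative_power(
            PowerSpectrum(freqs=GRID.copy(), ap=np.ones((4, 17)), n_epochs=1)
        )
        with pytest.raises(ParameterError):
            peak_frequency(rp_obj, band=(3.0, 10.0))

    def test_scale_invariance_of_full_chain(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(int(10 * FS), 4))
        r1 = make_recording(x)
        r2 = make_recording(1234.5 * x)
        _, _, rp1, pk1 = spectral.analyze_recording(r1, filter_band=None)
        _, _, rp2, pk2 = spectral.analyze_recording(r2, filter_band=None)
        assert np.allclose(rp1.rp, rp2.rp, rtol=1e-12)
        assert np.array_equal(pk1.peak_freq, pk2.peak_freq)
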