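"""Theta-band spectral analysis: epoching, artifact rejection, absolute and
relative power on the 4-12 Hz / 0.5 Hz grid, and peak-frequency extraction.

All spectra are means over 2-s epochs, which pins the DFT bin spacing to
exactly 0.5 Hz; the analysis grid is the 17 bins 4.0, 4.5, ..., 12.0 Hz.
Relative power (RP) expresses each bin as a percentage of the total 4-12 Hz
band power, so it sums to 100 per channel by construction and is invariant
to amplitude scaling of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .errors import (
    AllEpochsRejectedError,
    InsufficientDataError,
    ParameterError,
    ZeroPowerError,
)
from .simdata import CHANNELS, MultiSiteRecording

#: analysis grid: 4.0 .. 12.0 Hz inclusive in 0.5 Hz steps (17 bins)
GRID: np.ndarray = np.round(np.arange(4.0, 12.0 + 0.25, 0.5), 1)
EPOCH_LEN: float = 2.0
DEFAULT_PEAK_BAND: Tuple[float, float] = (5.0, 10.0)


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one recording.

    ``epochs`` is (n_epochs, n_channels, n_samples); ``kept`` marks epochs
    surviving artifact rejection and ``rejection_log`` records one
    (epoch_index, reason) entry per dropped epoch.
    """

    epochs: np.ndarray
    fs: float
    channel_labels: Tuple[str, ...] = CHANNELS
    meta: dict = field(default_factory=dict)
    kept: np.ndarray = None  # type: ignore[assignment]
    rejection_log: List[Tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.kept is None:
            self.kept = np.ones(self.epochs.shape[0], dtype=bool)

    @property
    def n_epochs(self) -> int:
        return int(self.epochs.shape[0])

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def kept_epochs(self) -> np.ndarray:
        return self.epochs[self.kept]


@dataclass
class PowerSpectrum:
    """Mean absolute power per 0.5 Hz bin per channel (AP)."""

    freqs: np.ndarray
    ap: np.ndarray  # (n_channels, 17)
    n_epochs: int
    channel_labels: Tuple[str, ...] = CHANNELS
    taper: str = "rect"
    meta: dict = field(default_factory=dict)


@dataclass
class RelativePower:
    """Per-bin power as percent of the 4-12 Hz band total (RP)."""

    freqs: np.ndarray
    rp: np.ndarray  # (n_channels, 17), rows sum to 100
    n_epochs: int
    channel_labels: Tuple[str, ...] = CHANNELS
    meta: dict = field(default_factory=dict)


@dataclass
class PeakSummary:
    """Location and height of the RP maximum within a search band."""

    peak_freq: np.ndarray  # per channel, Hz on the grid
    peak_rp: np.ndarray  # per channel, percent
    search_band: Tuple[float, float]
    channel_labels: Tuple[str, ...] = CHANNELS


def bandpass_filter(
    x: np.ndarray, fs: float, low: float = 1.0, high: float = 100.0
) -> np.ndarray:
    """Zero-phase Butterworth band-pass emulating the acquisition filters.

    The order is chosen (via ``buttord``, accounting for the forward-backward
    doubling of ``filtfilt``) so that the double-pass response keeps less
    than 1 dB ripple between 2 and 90 Hz and attenuates at least 20 dB at
    0.5 and 120 Hz for the default 1-100 Hz band.
    """
    if fs <= 2.0 * high:
        raise ParameterError(f"fs={fs} too low for a {high} Hz band edge (need fs > {2 * high})")
    if not (0 < low < high):
        raise ParameterError("need 0 < low < high")
    x = np.asarray(x, dtype=float)
    return sps.sosfiltfilt(_design_bandpass(float(fs), float(low), float(high)), x, axis=0)


@lru_cache(maxsize=16)
def _design_bandpass(fs: float, low: float, high: float) -> np.ndarray:
    wp = [2.0 * low, 0.9 * high]
    ws = [0.5 * low, 1.2 * high]
    n, wn = sps.buttord(wp, ws, gpass=0.4, gstop=10.5, fs=fs)
    return sps.butter(n, wn, btype="bandpass", output="sos", fs=fs)


def epoch_signal(
    recording: MultiSiteRecording,
    epoch_len: float = EPOCH_LEN,
    overlap: float = 0.0,
    max_duration: Optional[float] = None,
) -> EpochSet:
    """Cut consecutive fixed-length windows from t=0; the trailing partial
    window is discarded.

    ``max_duration`` truncates the recording first (used to drop the
    on-platform tail of search records); when omitted, a search recording's
    own ``search_duration`` metadata is honored.
    """
    if not (0.0 <= overlap < epoch_len):
        raise ParameterError("overlap must satisfy 0 <= overlap < epoch_len")
    data = recording.samples
    if max_duration is None:
        max_duration = recording.meta.get("search_duration")
    if max_duration is not None:
        n_max = int(round(min(max_duration, recording.duration) * recording.fs))
        data = data[:n_max]
    n_win = int(round(epoch_len * recording.fs))
    if abs(epoch_len * recording.fs - n_win) > 1e-9:
        raise ParameterError("fs * epoch_len must be an integer number of samples")
    if data.shape[0] < n_win:
        raise InsufficientDataError(
            f"recording portion ({data.shape[0] / recording.fs:.2f} s) shorter than one "
            f"{epoch_len} s epoch"
        )
    step = int(round((epoch_len - overlap) * recording.fs))
    starts = range(0, data.shape[0] - n_win + 1, step)
    epochs = np.stack([data[s : s + n_win].T for s in starts])  # (n_ep, n_ch, n_samp)
    return EpochSet(
        epochs=epochs,
        fs=recording.fs,
        channel_labels=tuple(recording.channel_labels),
        meta=dict(recording.meta),
    )


def reject_artifacts(epochs: EpochSet, z_threshold: float = 6.0) -> EpochSet:
    """Drop epochs whose peak absolute deviation exceeds ``z_threshold``
    robust standard deviations (median absolute deviation * 1.4826) of the
    whole recording, per channel.

    An automated stand-in for interactive visual artifact screening; every
    drop is logged and rejecting *all* epochs raises instead of silently
    returning an empty set.
    """
    if epochs.n_epochs < 1:
        raise InsufficientDataError("no epochs to screen")
    data = epochs.epochs  # (n_ep, n_ch, n_samp)
    flat = data.transpose(1, 0, 2).reshape(data.shape[1], -1)
    center = np.median(flat, axis=1)
    scale = 1.4826 * np.median(np.abs(flat - center[:, None]), axis=1)
    scale = np.where(scale > 0, scale, np.finfo(float).eps)
    kept = epochs.kept.copy()
    log = list(epochs.rejection_log)
    peaks = np.max(np.abs(data - center[None, :, None]), axis=2)  # (n_ep, n_ch)
    z = peaks / scale[None, :]
    for i in range(epochs.n_epochs):
        if not kept[i]:
            continue
        worst = int(np.argmax(z[i]))
        if z[i, worst] > z_threshold:
            kept[i] = False
            log.append(
                (i, f"amplitude {z[i, worst]:.1f} robust SD on {epochs.channel_labels[worst]}")
            )
    if not kept.any():
        raise AllEpochsRejectedError(
            f"artifact rejection removed all {epochs.n_epochs} epochs (z_threshold={z_threshold})"
        )
    return EpochSet(
        epochs=epochs.epochs,
        fs=epochs.fs,
        channel_labels=epochs.channel_labels,
        meta=epochs.meta,
        kept=kept,
        rejection_log=log,
    )


def _taper_window(taper: str, n: int) -> np.ndarray:
    if taper == "rect":
        return np.ones(n)
    if taper == "hann":
        return sps.windows.hann(n, sym=False)
    raise ParameterError(f"unknown taper {taper!r}; use 'rect' or 'hann'")


def _grid_indices(fs: float, n: int) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    idx = []
    for f in GRID:
        k = int(np.argmin(np.abs(freqs - f)))
        if abs(freqs[k] - f) > 1e-6:
            raise ParameterError(
                f"grid frequency {f} Hz does not fall on a DFT bin (spacing {fs / n} Hz)"
            )
        idx.append(k)
    return np.asarray(idx)


def epoch_spectra(epochs: EpochSet, taper: str = "rect") -> np.ndarray:
    """Complex DFT coefficients of every kept epoch on the 17-bin grid.

    Returns (n_kept, n_channels, 17); shared by the power and coherence
    estimators so both always see the same epochs.
    """
    if epochs.n_kept < 1:
        raise InsufficientDataError("need at least one kept epoch")
    data = epochs.kept_epochs()
    n = data.shape[2]
    w = _taper_window(taper, n)
    spec = np.fft.rfft(data * w[None, None, :], axis=2)
    return spec[:, :, _grid_indices(epochs.fs, n)]


def absolute_power(epochs: EpochSet, taper: str = "rect") -> PowerSpectrum:
    """Mean periodogram over kept 2-s epochs, restricted to the 4-12 Hz grid.

    Scaling convention: a unit-amplitude sinusoid on a grid frequency puts
    its power (0.5) in its own bin under the rectangular taper.
    """
    spec = epoch_spectra(epochs, taper=taper)
    n = epochs.epochs.shape[2]
    w = _taper_window(taper, n)
    ap = (2.0 / w.sum() ** 2) * np.mean(np.abs(spec) ** 2, axis=0)
    return PowerSpectrum(
        freqs=GRID.copy(),
        ap=ap,
        n_epochs=epochs.n_kept,
        channel_labels=epochs.channel_labels,
        taper=taper,
        meta=dict(epochs.meta),
    )


def relative_power(ps: PowerSpectrum) -> RelativePower:
    """RP per bin: 100 * AP / (total 4-12 Hz AP), per channel."""
    totals = ps.ap.sum(axis=1)
    for i, tot in enumerate(totals):
        if tot <= 0:
            raise ZeroPowerError(
                f"channel {ps.channel_labels[i]} has zero total 4-12 Hz power"
            )
    rp = 100.0 * ps.ap / totals[:, None]
    return RelativePower(
        freqs=ps.freqs.copy(),
        rp=rp,
        n_epochs=ps.n_epochs,
        channel_labels=ps.channel_labels,
        meta=dict(ps.meta),
    )


def log_absolute_power(ps: PowerSpectrum) -> Tuple[np.ndarray, np.ndarray]:
    """Natural log of AP; non-positive bins are flagged and set to NaN.

    Returns ``(nl_ap, excluded)`` where ``excluded`` is a boolean mask of
    bins that could not be log-transformed.
    """
    excluded = ps.ap <= 0
    nl = np.full_like(ps.ap, np.nan)
    nl[~excluded] = np.log(ps.ap[~excluded])
    return nl, excluded


def peak_frequency(
    rp: RelativePower, band: Tuple[float, float] = DEFAULT_PEAK_BAND
) -> PeakSummary:
    """Frequency of the RP maximum within ``band`` (ties -> lowest bin)."""
    lo, hi = band
    if lo < rp.freqs[0] or hi > rp.freqs[-1] or lo >= hi:
        raise ParameterError(f"band {band} must lie within the {rp.freqs[0]}-{rp.freqs[-1]} grid")
    mask = (rp.freqs >= lo - 1e-9) & (rp.freqs <= hi + 1e-9)
    sub = rp.rp[:, mask]
    idx = np.argmax(sub, axis=1)  # argmax returns the first (lowest) bin on ties
    freqs_band = rp.freqs[mask]
    return PeakSummary(
        peak_freq=freqs_band[idx],
        peak_rp=sub[np.arange(sub.shape[0]), idx],
        search_band=(lo, hi),
        channel_labels=rp.channel_labels,
    )


def analyze_recording(
    recording: MultiSiteRecording,
    taper: str = "rect",
    z_threshold: float = 6.0,
    band: Tuple[float, float] = DEFAULT_PEAK_BAND,
    filter_band: Optional[Tuple[float, float]] = (1.0, 100.0),
) -> Tuple[EpochSet, PowerSpectrum, RelativePower, PeakSummary]:
    """Full single-recording spectral chain: filter, epoch, reject, AP/RP/peak."""
    rec = recording
    if filter_band is not None:
        rec = MultiSiteRecording(
            samples=bandpass_filter(recording.samples, recording.fs, *filter_band),
            fs=recording.fs,
            channel_labels=recording.channel_labels,
            meta=dict(recording.meta),
        )
    epochs = reject_artifacts(epoch_signal(rec), z_threshold=z_threshold)
    ps = absolute_power(epochs, taper=taper)
    rp = relative_power(ps)
    peak = peak_frequency(rp, band=band)
    return epochs, ps, rp, peak
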