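"""Inter-region magnitude-squared coherence (MSC) and coherence-peak metrics.

MSC is estimated Welch-style on the same kept 2-s epochs the spectral module
uses::

    msc(f) = |<X(f) Y*(f)>|^2 / (<|X|^2> <|Y|^2>)

averaged over epochs and restricted to the 4-12 Hz / 0.5 Hz grid.  A single
segment yields MSC identically 1, so at least two kept epochs are required.
The estimator is positively biased for few segments (mean ~1/K for K
independent epochs), which is why short trials are excluded rather than
averaged in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

from .errors import DegenerateDataError, InsufficientDataError, ParameterError
from .simdata import MultiSiteRecording, canonical_pair
from .spectral import DEFAULT_PEAK_BAND, GRID, EpochSet, epoch_signal, epoch_spectra


@dataclass
class CoherenceSpectrum:
    """MSC on the 17-bin grid for one canonical region pair."""

    pair: Tuple[str, str]
    freqs: np.ndarray
    msc: np.ndarray
    n_epochs: int
    meta: dict = field(default_factory=dict)


@dataclass
class CoherencePeak:
    """Frequency (FCP) and magnitude of the coherence maximum in a band."""

    pair: Tuple[str, str]
    fcp: float
    magnitude: float
    band: Tuple[float, float]


@dataclass
class PeakCorrelation:
    """Pearson correlation of daily peak frequencies between two regions."""

    pair: Tuple[str, str]
    r: float
    p: float
    n: int


def coherence_spectrum(
    recording_or_epochs,
    pair: Tuple[str, str],
    epoch_len: float = 2.0,
    taper: str = "rect",
) -> CoherenceSpectrum:
    """Welch MSC between the two channels of ``pair``.

    Accepts either a :class:`MultiSiteRecording` (epoched internally with no
    artifact screening) or a pre-screened :class:`EpochSet`, so power and
    coherence can share identical epochs.
    """
    pair = canonical_pair(*pair)
    if isinstance(recording_or_epochs, MultiSiteRecording):
        epochs = epoch_signal(recording_or_epochs, epoch_len=epoch_len)
    elif isinstance(recording_or_epochs, EpochSet):
        epochs = recording_or_epochs
    else:
        raise ParameterError("expected a MultiSiteRecording or EpochSet")
    if epochs.n_kept < 2:
        raise InsufficientDataError(
            f"MSC needs at least 2 kept epochs (got {epochs.n_kept}); a single segment "
            "gives coherence identically 1"
        )
    spec = epoch_spectra(epochs, taper=taper)  # (n_kept, n_ch, 17)
    ia = epochs.channel_labels.index(pair[0])
    ib = epochs.channel_labels.index(pair[1])
    x, y = spec[:, ia, :], spec[:, ib, :]
    sxy = np.mean(x * np.conj(y), axis=0)
    sxx = np.mean(np.abs(x) ** 2, axis=0)
    syy = np.mean(np.abs(y) ** 2, axis=0)
    denom = sxx * syy
    msc = np.zeros_like(sxx)
    ok = denom > 0
    msc[ok] = np.abs(sxy[ok]) ** 2 / denom[ok]
    msc = np.clip(msc, 0.0, 1.0)
    return CoherenceSpectrum(
        pair=pair,
        freqs=GRID.copy(),
        msc=msc,
        n_epochs=epochs.n_kept,
        meta=dict(epochs.meta),
    )


def coherence_peak(
    cs: CoherenceSpectrum, band: Tuple[float, float] = DEFAULT_PEAK_BAND
) -> CoherencePeak:
    """Argmax of MSC within ``band`` (ties -> lowest frequency)."""
    lo, hi = band
    if lo < cs.freqs[0] or hi > cs.freqs[-1] or lo >= hi:
        raise ParameterError(f"band {band} outside the {cs.freqs[0]}-{cs.freqs[-1]} grid")
    mask = (cs.freqs >= lo - 1e-9) & (cs.freqs <= hi + 1e-9)
    sub = cs.msc[mask]
    k = int(np.argmax(sub))
    return CoherencePeak(
        pair=cs.pair, fcp=float(cs.freqs[mask][k]), magnitude=float(sub[k]), band=(lo, hi)
    )


def average_coherence(
    spectra: Sequence[CoherenceSpectrum], weighted: bool = True
) -> CoherenceSpectrum:
    """Combine per-trial MSC spectra of one pair into a daily spectrum.

    Default weights each trial by its epoch count (trials of unequal
    duration contribute proportionally to the data they carry); an
    unweighted mean is available for sensitivity checks.
    """
    if not spectra:
        raise InsufficientDataError("no coherence spectra to average")
    pair = spectra[0].pair
    for cs in spectra:
        if cs.pair != pair:
            raise ParameterError(f"mixed pairs in average: {cs.pair} vs {pair}")
    w = np.array([cs.n_epochs if weighted else 1.0 for cs in spectra], dtype=float)
    stack = np.stack([cs.msc for cs in spectra])
    msc = np.average(stack, axis=0, weights=w)
    return CoherenceSpectrum(
        pair=pair,
        freqs=spectra[0].freqs.copy(),
        msc=msc,
        n_epochs=int(sum(cs.n_epochs for cs in spectra)),
        meta={"n_trials": len(spectra), "weighted": weighted},
    )


def peak_frequency_correlation(
    daily_peaks_a: np.ndarray,
    daily_peaks_b: np.ndarray,
    pair: Tuple[str, str] = ("A", "B"),
) -> PeakCorrelation:
    """Pearson correlation of paired per-(subject, day) peak frequencies.

    Two-sided p from the exact t transform; zero variance in either series
    is an explicit error rather than a silent NaN.
    """
    a = np.asarray(daily_peaks_a, dtype=float)
    b = np.asarray(daily_peaks_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("peak series must be paired (same shape)")
    a, b = a.ravel(), b.ravel()
    if a.size < 3:
        raise InsufficientDataError(f"need at least 3 paired points, got {a.size}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise DegenerateDataError("correlation undefined: a series has zero variance")
    res = sstats.pearsonr(a, b)
    return PeakCorrelation(pair=tuple(pair), r=float(res.statistic), p=float(res.pvalue), n=a.size)
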