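"""Synthetic multi-site theta EEG and water-maze swim trajectories.

This module generates the ground-truth data the rest of the pipeline is
tested against: four-channel local-field-potential records (supramammillary
nucleus SUM, medial septum MS, dentate gyrus DG, hippocampal CA1) whose
dominant theta frequency, inter-site coherence and accompanying swim
behavior follow two cohort profiles:

* ``CTR`` — a learning profile: the dominant theta frequency climbs from
  ~7 Hz toward ~8 Hz across six training days, septo-hippocampal coherence
  rises, and swim paths shorten.
* ``EXP`` — a flat profile: frequency, coupling and behavior stay at their
  day-1 values, emulating a cohort whose learning-related theta dynamics
  are abolished.

The EEG model is deliberately phenomenological, not biophysical.  Each
channel is a weighted sum of

1. a *shared* narrowband theta driver (a stochastically driven second-order
   resonance at the scheduled frequency ``f0``),
2. an *independent* narrowband process with the same spectrum, and
3. broadband 1/f^alpha background noise.

For a channel pair sharing one driver, ``x = s + g1*n1`` and
``y = s + g2*n2`` with per-channel noise set so that the magnitude-squared
coherence (MSC) at the driver bin equals the configured target
``gamma2 = (SNR/(1+SNR))**2`` where ``SNR`` is the driver-to-independent
power ratio at that bin.  This gives an analytic handle on every quantity
the downstream estimators are supposed to recover.

Swim behavior is a biased correlated random walk at constant speed inside a
circular pool: the heading relaxes toward the bearing of the (hidden)
platform with gain ``bias_gain`` and is perturbed by Gaussian heading
noise.  Learning is emulated by raising the gain across days.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, ParameterError, SchemaError

# Canonical channel order and region-pair naming (alphabetical within pair).
CHANNELS: Tuple[str, ...] = ("SUM", "MS", "DG", "CA1")
GROUPS: Tuple[str, str] = ("CTR", "EXP")


def canonical_pair(a: str, b: str) -> Tuple[str, str]:
    """Return the canonical (alphabetical) ordering of a region pair."""
    if a == b:
        raise ParameterError(f"a region pair needs two distinct regions, got {a!r} twice")
    for r in (a, b):
        if r not in CHANNELS:
            raise ParameterError(f"unknown region {r!r}; expected one of {CHANNELS}")
    return (a, b) if a < b else (b, a)


PAIRS: Tuple[Tuple[str, str], ...] = tuple(
    sorted(tuple(sorted(p)) for p in itertools.combinations(CHANNELS, 2))
)

THETA_BAND = (4.0, 12.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoolGeometry:
    """Circular Morris-maze pool with a hidden escape platform.

    Defaults: 1.5 m diameter pool, 9 cm diameter platform centered halfway
    out along the north radius (the platform quadrant).
    """

    radius: float = 0.75
    platform_center: Tuple[float, float] = (0.0, 0.375)
    platform_radius: float = 0.045
    quadrant_labels: Tuple[str, str, str, str] = ("N", "S", "E", "W")

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError("pool radius must be positive")
        px, py = self.platform_center
        if math.hypot(px, py) + self.platform_radius > self.radius:
            raise ParameterError("platform must lie entirely inside the pool")


@dataclass
class SwimTrajectory:
    """Timestamped planar swim path.

    ``points`` is an (n, 3) array of columns (t [s], x [m], y [m]); ``meta``
    carries subject / group / day / trial / probe bookkeeping plus the
    simulator's ground-truth ``latency`` and ``guided`` flag when generated
    synthetically.
    """

    points: np.ndarray
    pool: PoolGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise SchemaError("trajectory points must be an (n, 3) array of (t, x, y)")
        t = self.points[:, 0]
        if np.any(np.diff(t) <= 0):
            raise SchemaError("trajectory timestamps must be strictly increasing")
        r2 = self.points[:, 1] ** 2 + self.points[:, 2] ** 2
        if np.any(r2 > self.pool.radius**2 * (1 + 1e-9)):
            raise SchemaError("trajectory leaves the pool")

    @property
    def t(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, 1:3]

    @property
    def duration(self) -> float:
        return float(self.points[-1, 0] - self.points[0, 0])


@dataclass
class MultiSiteRecording:
    """One trial's 4-channel EEG plus study-design metadata.

    ``samples`` is (n_samples, 4) in arbitrary amplitude units; channels are
    ordered ``("SUM", "MS", "DG", "CA1")``.  ``meta`` holds subject, group,
    day, trial, condition (``basal`` or ``search``) and, for search records,
    ``search_duration`` — the pre-platform portion analyzed downstream.
    """

    samples: np.ndarray
    fs: float
    channel_labels: Tuple[str, ...] = CHANNELS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.channel_labels):
            raise SchemaError(
                f"samples must be (n, {len(self.channel_labels)}); got {self.samples.shape}"
            )
        if len(self.channel_labels) != 4:
            raise SchemaError("exactly 4 channels are required")
        if not np.all(np.isfinite(self.samples)):
            bad = np.argwhere(~np.isfinite(self.samples))
            raise SchemaError(f"non-finite samples at rows {bad[:5, 0].tolist()}...")
        cond = self.meta.get("condition")
        if cond == "basal" and abs(self.duration - 60.0) > 1e-6:
            raise SchemaError("basal recordings must be exactly 60 s")
        if cond == "search" and self.duration > 75.0 + 1e-9:
            raise SchemaError("search recordings must not exceed 75 s")

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise SchemaError(f"channel {label!r} not present in {self.channel_labels}")
        return self.samples[:, idx]


def _default_peak_schedule() -> Dict[str, List[float]]:
    # CTR: dominant theta climbs 7 -> 8 Hz across the six training days;
    # EXP: stays at the day-1 value.
    return {
        "CTR": [7.0, 7.25, 7.5, 7.5, 7.75, 8.0],
        "EXP": [7.0] * 6,
    }


def _default_coupling() -> Dict[Tuple[str, str], Dict[str, List[float]]]:
    """Target MSC per (pair, group, day). Septo-hippocampal pairs rise in CTR."""
    flat_ctr = [0.35] * 6
    rising = [0.30, 0.37, 0.44, 0.51, 0.58, 0.65]
    coupling: Dict[Tuple[str, str], Dict[str, List[float]]] = {}
    for pair in PAIRS:
        coupling[pair] = {"CTR": list(flat_ctr), "EXP": [0.30] * 6}
    coupling[("CA1", "MS")]["CTR"] = list(rising)
    coupling[("DG", "MS")]["CTR"] = list(rising)
    return coupling


def _default_bias_schedule() -> Dict[str, List[float]]:
    # Platform-bearing gain of the swim walk; the CTR ramp emulates place
    # learning, the flat EXP profile its absence.
    return {
        "CTR": [0.05, 0.10, 0.20, 0.30, 0.50, 0.70],
        "EXP": [0.08] * 6,
    }


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort.

    The defaults encode the study conditions: 7 CTR and 6 EXP subjects, six
    training days of four trials, a probe on day 7, 1024 Hz sampling, a
    0.5 Hz-bandwidth theta oscillator over 1/f background at a band SNR of 3
    during search (1.5 when awake-immobile in the cage).
    """

    fs: float = 1024.0
    n_subjects: Mapping[str, int] = field(default_factory=lambda: {"CTR": 7, "EXP": 6})
    days: int = 6
    trials_per_day: int = 4
    peak_schedule: Dict[str, List[float]] = field(default_factory=_default_peak_schedule)
    shift_profile: Optional[dict] = None
    coupling: Dict[Tuple[str, str], Dict[str, List[float]]] = field(
        default_factory=_default_coupling
    )
    oscillator_bandwidth: float = 0.5
    noise_exponent: float = 1.0
    snr: float = 3.0
    basal_snr: float = 1.5
    amplitude: float = 1.0
    swim_speed: float = 0.25
    swim_dt: float = 0.1
    heading_noise: float = 1.0
    bias_schedule: Dict[str, List[float]] = field(default_factory=_default_bias_schedule)
    include_platform_period: bool = False
    pool: PoolGeometry = field(default_factory=PoolGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or abs(self.fs * 2.0 - round(self.fs * 2.0)) > 1e-9:
            raise ConfigurationError("fs must be positive with fs * 2 s an integer sample count")
        for group, sched in self.peak_schedule.items():
            if len(sched) < self.days:
                raise ConfigurationError(f"peak_schedule[{group}] shorter than {self.days} days")
            for f0 in sched:
                if not (THETA_BAND[0] <= f0 <= THETA_BAND[1]):
                    raise ConfigurationError(f"f0={f0} outside the {THETA_BAND} Hz theta band")
        for pair, per_group in self.coupling.items():
            if canonical_pair(*pair) != tuple(pair):
                raise ConfigurationError(f"coupling pair {pair} not in canonical order")
            for group, targets in per_group.items():
                for g2 in targets:
                    if not (0.0 <= g2 <= 1.0):
                        raise ConfigurationError(
                            f"coherence target {g2} for pair {pair}, group {group} not in [0, 1]"
                        )
        if self.snr <= 0 or self.basal_snr <= 0:
            raise ConfigurationError("snr must be positive")

    # -- schedule lookups (day 7, the probe, reuses the day-6 entry) -------

    def _day_index(self, day: int) -> int:
        if not (1 <= day <= self.days + 1):
            raise ConfigurationError(f"day {day} outside schedule 1..{self.days + 1}")
        return min(day, self.days) - 1

    def f0_for(self, group: str, day: int) -> float:
        return float(self.peak_schedule[group][self._day_index(day)])

    def coupling_for(self, pair: Tuple[str, str], group: str, day: int) -> float:
        pair = canonical_pair(*pair)
        return float(self.coupling[pair][group][self._day_index(day)])

    def bias_for(self, group: str, day: int) -> float:
        return float(self.bias_schedule[group][self._day_index(day)])


# ---------------------------------------------------------------------------
# Elementary signal generators
# ---------------------------------------------------------------------------


def _resonator_coeffs(f0: float, bandwidth: float, fs: float) -> Tuple[np.ndarray, np.ndarray]:
    r = math.exp(-math.pi * bandwidth / fs)
    w = 2.0 * math.pi * f0 / fs
    return np.array([1.0]), np.array([1.0, -2.0 * r * math.cos(w), r * r])


def make_theta_oscillator(
    f0: float,
    bandwidth: float,
    duration: float,
    fs: float,
    seed=None,
    variance: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Zero-mean narrowband stochastic signal with spectral peak at ``f0``.

    A white-noise-driven second-order resonance (pole radius set by
    ``bandwidth``, the approximate full width of the spectral peak in Hz).
    ``bandwidth=0`` degenerates to a pure sinusoid with random phase.  The
    output is normalized to the requested ``variance`` exactly.
    """
    if not (0.0 < f0 < fs / 2.0):
        raise ParameterError(f"f0={f0} Hz must lie in (0, {fs / 2}) Hz")
    if bandwidth < 0:
        raise ParameterError("bandwidth must be >= 0")
    if duration <= 0:
        raise ParameterError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    if bandwidth == 0.0:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        t = np.arange(n) / fs
        return math.sqrt(2.0 * variance) * np.sin(2.0 * math.pi * f0 * t + phase)
    b, a = _resonator_coeffs(f0, bandwidth, fs)
    # discard the filter transient: ~8 time constants of the pole decay
    burn = int(math.ceil(8.0 * fs / (math.pi * bandwidth)))
    x = sps.lfilter(b, a, rng.standard_normal(n + burn))[burn:]
    x -= x.mean()
    sd = x.std()
    if sd == 0.0:  # pragma: no cover - white drive makes this impossible
        raise ParameterError("degenerate oscillator output")
    return x * (math.sqrt(variance) / sd)


def one_over_f_noise(
    duration: float,
    fs: float,
    exponent: float = 1.0,
    seed=None,
    variance: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    white_fraction: float = 0.05,
    f_floor: float = 1.0,
) -> np.ndarray:
    """1/f^alpha background noise with a white floor, unit-variance normalized.

    Spectral amplitudes are shaped as ``sqrt(max(f, f_floor)^-alpha + white)``
    so the PSD is known in closed form on the analysis grid.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = _bg_amplitude(freqs, exponent, white_fraction, f_floor)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    sd = x.std()
    return x * (math.sqrt(variance) / sd)


def _bg_amplitude(
    freqs: np.ndarray, exponent: float, white_fraction: float = 0.05, f_floor: float = 1.0
) -> np.ndarray:
    f = np.maximum(np.asarray(freqs, dtype=float), f_floor)
    return np.sqrt(f ** (-exponent) + white_fraction)


def _oscillator_psd_ratio(config: SimConfig, f0: float) -> float:
    """PSD of unit-variance background over unit-variance oscillator at f0.

    Both PSDs are evaluated on a dense grid and normalized to unit total
    variance, so the ratio is scale-free; it feeds the coherence correction
    that accounts for broadband noise leaking into the driver bin.
    """
    n_grid = 8192
    freqs = np.linspace(0.0, config.fs / 2.0, n_grid)
    b, a = _resonator_coeffs(f0, config.oscillator_bandwidth, config.fs)
    _, h = sps.freqz(b, a, worN=freqs, fs=config.fs)
    psd_osc = np.abs(h) ** 2
    psd_osc /= np.trapezoid(psd_osc, freqs)
    psd_bg = _bg_amplitude(freqs, config.noise_exponent) ** 2
    psd_bg /= np.trapezoid(psd_bg, freqs)
    idx = int(np.argmin(np.abs(freqs - f0)))
    return float(psd_bg[idx] / psd_osc[idx])


def _bg_band_fraction(config: SimConfig) -> float:
    """Fraction of background variance falling inside the 4-12 Hz band."""
    n_grid = 8192
    freqs = np.linspace(0.0, config.fs / 2.0, n_grid)
    psd = _bg_amplitude(freqs, config.noise_exponent) ** 2
    band = (freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1])
    return float(np.trapezoid(psd[band], freqs[band]) / np.trapezoid(psd, freqs))


# ---------------------------------------------------------------------------
# Coherence plumbing
# ---------------------------------------------------------------------------


def coherent_pair(
    gamma2: float,
    f0: float,
    bandwidth: float,
    duration: float,
    fs: float,
    seed=None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Two signals whose MSC equals ``gamma2`` by construction.

    ``x = s + g*n1``, ``y = s + g*n2`` where ``s``, ``n1``, ``n2`` are
    independent unit-variance oscillators of identical spectral shape, and
    ``g**2 = (1 - sqrt(gamma2)) / sqrt(gamma2)``.  Because the shapes match,
    the theoretical MSC equals ``gamma2`` at *every* frequency, in
    particular at the driver bin.
    """
    if not (0.0 <= gamma2 <= 1.0):
        raise ParameterError("gamma2 must lie in [0, 1]")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
    s = make_theta_oscillator(f0, bandwidth, duration, fs, rng=rngs[0])
    if gamma2 == 1.0:
        return s, s.copy()
    gamma = math.sqrt(gamma2)
    if gamma == 0.0:
        x = make_theta_oscillator(f0, bandwidth, duration, fs, rng=rngs[1])
        y = make_theta_oscillator(f0, bandwidth, duration, fs, rng=rngs[2])
        return x, y
    g = math.sqrt((1.0 - gamma) / gamma)
    n1 = make_theta_oscillator(f0, bandwidth, duration, fs, rng=rngs[1])
    n2 = make_theta_oscillator(f0, bandwidth, duration, fs, rng=rngs[2])
    return s + g * n1, s + g * n2


def _solve_channel_mixing(targets: Mapping[Tuple[str, str], float]) -> Dict[str, float]:
    """Per-channel shared-driver coupling ``c_i`` from pairwise MSC targets.

    With one driver shared by all four channels, the realizable pairwise MSC
    is ``c_i * c_j`` where ``c_i = SNR_i / (1 + SNR_i)`` at the driver bin.
    The 6 targets over-determine the 4 unknowns; we solve the least-squares
    problem in log space and reject configurations whose best fit misses a
    target by more than 0.25 (absolute MSC), naming the offending pair.
    """
    targets = {canonical_pair(*p): float(v) for p, v in targets.items()}
    vals = np.array([targets[p] for p in PAIRS])
    if np.all(vals == 0.0):
        return {ch: 0.0 for ch in CHANNELS}
    if np.any(vals == 0.0):
        bad = PAIRS[int(np.argmin(vals))]
        raise ConfigurationError(
            f"coupling target 0 for pair {bad} cannot be realized by a single shared driver "
            "while other pairs are coupled"
        )
    rows, rhs = [], []
    for k, pair in enumerate(PAIRS):
        row = np.zeros(len(CHANNELS))
        row[CHANNELS.index(pair[0])] = 1.0
        row[CHANNELS.index(pair[1])] = 1.0
        rows.append(row)
        rhs.append(math.log(vals[k]))
    sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    c = {ch: float(min(1.0, math.exp(sol[i]))) for i, ch in enumerate(CHANNELS)}
    for pair in PAIRS:
        realized = c[pair[0]] * c[pair[1]]
        if abs(realized - targets[pair]) > 0.25:
            raise ConfigurationError(
                f"coupling matrix not realizable by a single shared driver: pair {pair} "
                f"target {targets[pair]:.3f}, best fit {realized:.3f}"
            )
    return c


# ---------------------------------------------------------------------------
# Trial-level simulators
# ---------------------------------------------------------------------------


def simulate_trial_eeg(
    config: SimConfig,
    subject: str,
    group: str,
    day: int,
    trial: int,
    condition: str = "search",
    duration: float = 60.0,
    seed=None,
) -> MultiSiteRecording:
    """One trial's 4-channel EEG under the configured group/day profile.

    Each channel mixes the shared theta driver, an independent same-spectrum
    process and 1/f^alpha background.  The independent-noise gains are set so
    that the pairwise MSC at the driver bin matches the coupling schedule
    (least-squares compromise across the six pairs; the broadband
    background's contribution at the driver bin is subtracted from the
    narrowband noise budget, clipping at zero).
    """
    if duration < 2.0:
        raise ParameterError("EEG trial duration must be at least 2 s (one epoch)")
    if group not in config.peak_schedule:
        raise ConfigurationError(f"unknown group {group!r}")
    f0 = config.f0_for(group, day)
    targets = {pair: config.coupling_for(pair, group, day) for pair in PAIRS}
    c = _solve_channel_mixing(targets)

    snr_band = config.basal_snr if condition == "basal" else config.snr
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child = ss.spawn(2 + 2 * len(CHANNELS))
    rng_driver = np.random.default_rng(child[0])

    bw = config.oscillator_bandwidth
    if config.shift_profile is not None:
        prof = config.shift_profile[group]
        w_low, w_high = prof["weights"][config._day_index(day)]
        s_low = make_theta_oscillator(prof["f_low"], bw, duration, config.fs, rng=rng_driver)
        s_high = make_theta_oscillator(
            prof["f_high"], bw, duration, config.fs, rng=np.random.default_rng(child[1])
        )
        s = w_low * s_low + w_high * s_high
        sd = s.std()
        s = s / sd if sd > 0 else s
        f0 = prof["f_high"] if w_high >= w_low else prof["f_low"]
    else:
        s = make_theta_oscillator(f0, bw, duration, config.fs, rng=rng_driver)

    # background PSD at the driver bin, relative to the oscillator PSD,
    # after scaling the background to the configured band SNR
    beta2 = 1.0 / (snr_band * _bg_band_fraction(config))
    rho_bg = beta2 * _oscillator_psd_ratio(config, f0)

    n = int(round(duration * config.fs))
    samples = np.empty((n, len(CHANNELS)))
    for i, ch_name in enumerate(CHANNELS):
        rng_n = np.random.default_rng(child[2 + 2 * i])
        rng_bg = np.random.default_rng(child[3 + 2 * i])
        ci = c[ch_name]
        bg = one_over_f_noise(
            duration,
            config.fs,
            config.noise_exponent,
            rng=rng_bg,
            variance=beta2,
        )
        if ci <= 0.0:
            ch = make_theta_oscillator(f0, bw, duration, config.fs, rng=rng_n) + bg
        elif ci >= 1.0:
            ch = s + bg * 0.0  # fully coherent channel: no independent part at all
        else:
            g2 = max(0.0, (1.0 - ci) / ci - rho_bg)
            ch = s + bg
            if g2 > 0.0:
                ch = ch + math.sqrt(g2) * make_theta_oscillator(
                    f0, bw, duration, config.fs, rng=rng_n
                )
        samples[:, i] = config.amplitude * ch

    meta = {
        "subject": subject,
        "group": group,
        "day": int(day),
        "trial": int(trial),
        "condition": condition,
        "f0": f0,
        "coupling_targets": targets,
    }
    return MultiSiteRecording(samples=samples, fs=config.fs, meta=meta)


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def simulate_swim_trial(
    pool: PoolGeometry,
    bias_gain: float,
    speed: float = 0.25,
    max_duration: float = 60.0,
    seed=None,
    dt: float = 0.1,
    heading_noise: float = 1.0,
    start_angle: Optional[float] = None,
    probe: bool = False,
    probe_duration: float = 30.0,
    meta: Optional[dict] = None,
) -> SwimTrajectory:
    """Biased correlated random walk at constant speed inside the pool.

    Each step the heading relaxes toward the bearing of the platform (or the
    remembered platform location on probe trials) with weight
    ``min(1, bias_gain)`` and receives Gaussian noise of standard deviation
    ``heading_noise / (1 + bias_gain)`` radians.  A step that would exit the
    pool is specularly reflected off the wall.  Non-probe trials end at
    platform entry or at ``max_duration`` (``guided`` flag set); probe
    trials run for the fixed ``probe_duration`` with no platform present.
    """
    if speed <= 0:
        raise ParameterError("speed must be positive")
    if bias_gain < 0:
        raise ParameterError("bias_gain must be >= 0")
    if speed * dt > pool.radius:
        raise ParameterError("step size speed*dt exceeds the pool radius")
    rng = np.random.default_rng(seed)
    if start_angle is None:
        start_angle = rng.uniform(0.0, 2.0 * math.pi)
    r_wall = pool.radius * 0.995
    pos = np.array([r_wall * math.cos(start_angle), r_wall * math.sin(start_angle)])
    heading = _wrap_angle(start_angle + math.pi)  # facing the pool center
    target = np.asarray(pool.platform_center, dtype=float)
    total = probe_duration if probe else max_duration
    n_steps = int(round(total / dt))
    w = min(1.0, bias_gain)
    sigma = heading_noise / (1.0 + bias_gain)

    pts = [(0.0, pos[0], pos[1])]
    latency = None
    for k in range(1, n_steps + 1):
        bearing = math.atan2(target[1] - pos[1], target[0] - pos[0])
        heading = _wrap_angle(heading + w * _wrap_angle(bearing - heading) + sigma * rng.standard_normal())
        step = speed * dt * np.array([math.cos(heading), math.sin(heading)])
        new = pos + step
        rad = np.hypot(new[0], new[1])
        if rad > r_wall:
            normal = new / rad
            v = step / np.linalg.norm(step)
            v = v - 2.0 * float(v @ normal) * normal
            heading = math.atan2(v[1], v[0])
            new = normal * r_wall
        pos = new
        t = k * dt
        pts.append((t, pos[0], pos[1]))
        if not probe and np.hypot(*(pos - target)) <= pool.platform_radius:
            latency = t
            break
    guided = False
    if not probe and latency is None:
        latency = float(total)
        guided = True
    traj_meta = dict(meta or {})
    traj_meta.update(
        {
            "probe": bool(probe),
            "latency": None if probe else float(latency),
            "guided": guided,
            "bias_gain": float(bias_gain),
            "start_angle": float(start_angle),
        }
    )
    return SwimTrajectory(points=np.asarray(pts), pool=pool, meta=traj_meta)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """All synthetic records of one simulated study."""

    recordings: List[MultiSiteRecording]
    trajectories: List[SwimTrajectory]
    config: SimConfig
    seed: int

    def manifest(self):
        import pandas as pd

        rows = []
        for i, rec in enumerate(self.recordings):
            m = rec.meta
            rows.append(
                {
                    "kind": "eeg",
                    "index": i,
                    "subject": m["subject"],
                    "group": m["group"],
                    "day": m["day"],
                    "trial": m["trial"],
                    "condition": m["condition"],
                    "duration_s": rec.duration,
                    "search_duration_s": m.get("search_duration"),
                    "probe": m.get("probe", False),
                }
            )
        for i, tr in enumerate(self.trajectories):
            m = tr.meta
            rows.append(
                {
                    "kind": "trajectory",
                    "index": i,
                    "subject": m["subject"],
                    "group": m["group"],
                    "day": m["day"],
                    "trial": m["trial"],
                    "condition": "probe" if m.get("probe") else "search",
                    "duration_s": tr.duration,
                    "search_duration_s": m.get("latency"),
                    "probe": m.get("probe", False),
                }
            )
        return pd.DataFrame(rows)


def _quadrant_bisectors() -> Dict[str, float]:
    return {"E": 0.0, "N": math.pi / 2.0, "W": math.pi, "S": -math.pi / 2.0}


def simulate_cohort(
    config: SimConfig,
    seed: Optional[int] = None,
    groups: Optional[Sequence[str]] = None,
    conditions: Sequence[str] = ("basal", "search"),
    with_probe: bool = True,
    with_behavior: bool = True,
) -> Cohort:
    """Simulate the full study: per subject and day, one 60 s basal record
    plus four search trials (EEG duration tied to the swim latency), and a
    30 s probe pair on day 7.

    Start positions follow the study protocol: the four wall-start quadrants
    are used once each per day in an order drawn per day but shared by every
    subject that day.  ``conditions`` / ``with_probe`` / ``with_behavior``
    allow scaled-down cohorts (e.g. spectra-only Monte-Carlo harnesses).
    """
    if seed is None:
        seed = config.seed
    if groups is None:
        groups = list(config.n_subjects.keys())
    root = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(root.spawn(1)[0])
    bisectors = _quadrant_bisectors()
    labels = list(bisectors)
    start_order = [list(order_rng.permutation(labels)) for _ in range(config.days)]

    recordings: List[MultiSiteRecording] = []
    trajectories: List[SwimTrajectory] = []
    subj_counter = 0
    for group in groups:
        for s_idx in range(config.n_subjects[group]):
            subject = f"{group}{s_idx + 1:02d}"
            subj_counter += 1
            subj_ss = np.random.SeedSequence([seed, 1000 + subj_counter])
            day_seeds = subj_ss.spawn(config.days + 1)
            for day in range(1, config.days + 1):
                trial_seeds = day_seeds[day - 1].spawn(2 * config.trials_per_day + 1)
                if "basal" in conditions:
                    recordings.append(
                        simulate_trial_eeg(
                            config,
                            subject,
                            group,
                            day,
                            trial=0,
                            condition="basal",
                            duration=60.0,
                            seed=trial_seeds[-1],
                        )
                    )
                for trial in range(1, config.trials_per_day + 1):
                    latency = 60.0
                    if with_behavior:
                        traj = simulate_swim_trial(
                            config.pool,
                            bias_gain=config.bias_for(group, day),
                            speed=config.swim_speed,
                            max_duration=60.0,
                            seed=trial_seeds[2 * (trial - 1)],
                            dt=config.swim_dt,
                            heading_noise=config.heading_noise,
                            start_angle=bisectors[start_order[day - 1][trial - 1]],
                            meta={"subject": subject, "group": group, "day": day, "trial": trial},
                        )
                        trajectories.append(traj)
                        latency = traj.meta["latency"]
                    if "search" in conditions:
                        eeg_duration = max(latency, 2.0)
                        if config.include_platform_period:
                            eeg_duration = min(latency + 15.0, 75.0)
                        rec = simulate_trial_eeg(
                            config,
                            subject,
                            group,
                            day,
                            trial,
                            condition="search",
                            duration=eeg_duration,
                            seed=trial_seeds[2 * (trial - 1) + 1],
                        )
                        rec.meta["search_duration"] = float(latency)
                        recordings.append(rec)
            # day-7 probe
            if with_probe:
                probe_seeds = day_seeds[config.days].spawn(2)
                probe_day = config.days + 1
                if with_behavior:
                    traj = simulate_swim_trial(
                        config.pool,
                        bias_gain=config.bias_for(group, config.days),
                        speed=config.swim_speed,
                        seed=probe_seeds[0],
                        dt=config.swim_dt,
                        heading_noise=config.heading_noise,
                        probe=True,
                        meta={
                            "subject": subject,
                            "group": group,
                            "day": probe_day,
                            "trial": 1,
                        },
                    )
                    trajectories.append(traj)
                if "search" in conditions:
                    rec = simulate_trial_eeg(
                        config,
                        subject,
                        group,
                        probe_day,
                        trial=1,
                        condition="search",
                        duration=30.0,
                        seed=probe_seeds[1],
                    )
                    rec.meta["probe"] = True
                    rec.meta["search_duration"] = 30.0
                    recordings.append(rec)
    return Cohort(recordings=recordings, trajectories=trajectories, config=config, seed=seed)
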