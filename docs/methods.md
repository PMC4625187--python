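# Methods

This note documents the models, estimators, parameter choices and known
limitations of the `thetamaze` package in one place.

## Synthetic EEG model

Each 4-channel record (SUM, MS, DG, CA1; 1024 Hz) is a sum of three parts
per channel:

1. **Shared theta driver** `s(t)`: white noise filtered by a second-order
   resonance with poles at radius `exp(-π·bw/fs)` and angle `2π·f0/fs`.
   The resonance gives a controllable spectral width (`bw`, default 0.5 Hz,
   roughly the full width of the peak) and a stochastic, realistic-looking
   rhythm; `bw = 0` degenerates to a pure sinusoid. Realizations are
   normalized to their target variance exactly, so configured
   oscillation-to-noise ratios hold per trial rather than only in
   expectation.
2. **Independent narrowband noise** `g·n(t)` with the same spectral shape
   as the driver, one independent realization per channel.
3. **1/f^α background** (α = 1 by default) with a small white floor,
   generated by explicit spectral shaping so its PSD is known in closed
   form; its variance is set so that the oscillator-to-background power
   ratio inside 4–12 Hz equals the configured band SNR (3.0 during search,
   1.5 for the awake-immobile basal condition).

Because driver and independent noise share one spectral shape, the
channel-pair coherence is analytic: with per-channel coupling
`c = SNR/(1+SNR)` at the driver bin, the magnitude-squared coherence of a
pair is `c_i · c_j`. Six pairwise targets over-determine the four
per-channel couplings, so the generator solves the least-squares problem in
log space; a best fit that misses any target by more than 0.25 raises a
configuration error naming the pair. Uniform targets are reproduced
exactly; the default schedule (septo-hippocampal pairs rising from 0.30 to
0.65 across days in the learning profile, everything else flat) is realized
as a compromise — the rise is preserved, absolute levels shift by up to
~0.1. This single-shared-driver simplification is a documented limitation:
arbitrary coherence *matrices* are not representable. The broadband
background also leaks power into the driver bin; its analytically known PSD
is subtracted from the narrowband noise budget (clipped at zero) so
realized coherence stays on target.

**Group profiles.** The learning (`CTR`) profile moves the driver frequency
through 7.0, 7.25, 7.5, 7.5, 7.75, 8.0 Hz over the six training days —
endpoints on the 0.5 Hz analysis grid, a one-bin-per-~2-days climb — while
the flat (`EXP`) profile stays at 7.0 Hz. A two-driver mixture
(`shift_profile`: separate "low" and "high" theta oscillators with per-day
weights) is available as an alternative mechanism. Day 7 (probe) reuses the
day-6 parameters.

## Swim model

A biased correlated random walk at constant speed (0.25 m/s; the study
reports velocities did not change and prints no value) with step `dt` =
0.1 s inside a 0.75 m-radius pool. Per step the heading relaxes toward the
platform bearing with weight `min(1, gain)` and receives Gaussian noise of
SD `1.0/(1+gain)` rad; steps that would exit the pool reflect specularly
off the wall. The heading-noise scale was set so that an unbiased walk
(gain 0) times out in well over half of trials — a naive animal rarely
crosses the 9 cm platform by chance — and so that the default gain
schedules produce day-1 mean latencies near 40 s. Learning is the gain
ramp 0.05 → 0.70 across days (`CTR`); the flat profile keeps gain 0.08,
which reproduces persistently long, variable latencies. Trials end at
platform entry or 60 s (the trial is then flagged `guided`, latency 60 s,
and kept in the means); probe trials run 30 s with the platform removed and
the bias aimed at the remembered location. Starts are on the wall at the
four quadrant bisectors, one per quadrant per day, in an order drawn per
day and shared by all subjects that day.

Search-EEG duration is tied to the swim latency of the same trial (floored
at one 2-s epoch). The 15 s the animal spends on the platform after each
trial is not generated by default, because the analyses use only the
pre-platform search period; `include_platform_period=True` appends it and
the analysis chain then trims to the `search_duration` metadata.

## Spectral chain

- **Acquisition filter**: zero-phase Butterworth band-pass, 1–100 Hz; the
  order is chosen via `buttord` (accounting for forward–backward doubling)
  to keep <1 dB ripple in 2–90 Hz and ≥20 dB attenuation at 0.5 and 120 Hz.
- **Epochs**: consecutive non-overlapping 2-s windows from t = 0, trailing
  remainder discarded. 2 s pins the DFT bin spacing to exactly 0.5 Hz; the
  analysis grid is 4.0–12.0 Hz inclusive (17 bins). The default rectangular
  taper matches the plain-FFT convention; Hann is available.
- **Artifact screening**: an epoch is dropped when its peak absolute
  deviation exceeds 6 robust SDs (median absolute deviation × 1.4826) of
  the whole recording on any channel. This replaces interactive visual
  screening with a reproducible rule; every drop is logged with its reason
  and rejecting all epochs is an explicit error.
- **AP scaling**: a unit-amplitude on-grid sinusoid contributes its power
  (0.5) to a single bin. Absolute units are arbitrary throughout — only RP,
  logs and coherence are compared.
- **Peak band**: RP comparisons and peak extraction use 5–10 Hz (11 bins);
  ties resolve to the lowest frequency. Daily peak frequency is the mean of
  the four trial peaks.

## Coherence

Welch MSC on the same kept epochs as the power estimates. At least two
epochs are required (one segment gives MSC ≡ 1), and the estimator's
small-sample bias — mean ≈ 1/K for K independent segments — is the reason
trials shorter than 4 s are excluded from coherence rather than averaged
in. Daily values are epoch-count-weighted means over the day's trials
(unweighted available), since trials of unequal duration carry unequal
information; whether the original analysis averaged per trial or
concatenated per day is not documented, so both routes exist with the
weighted per-trial route as default. FCP uses the same 5–10 Hz band and tie
rule as the RP peak.

## Statistics

- Friedman (tie-corrected mid-ranks), paired Wilcoxon and Mann–Whitney U
  use exact null distributions for small samples (n ≤ 25, no ties) and the
  tie-corrected normal approximation otherwise; the method used is recorded
  in each result.
- The randomized-block ANOVA and the repeated-measures engine are direct
  balanced sums-of-squares decompositions (subject-centered profiles split
  per within factor into effect / group×effect / subject×effect strata),
  supporting one or two within factors plus an optional between-subjects
  group with unequal group sizes. Tukey HSD uses the studentized range on
  the block error term.
- Sphericity: uncorrected degrees of freedom are reported by default;
  `gg=True` applies the Greenhouse–Geisser epsilon estimated from
  orthonormal-contrast covariances pooled within groups. The pipeline's
  day × frequency RP ANOVAs default to the GG correction because
  neighboring RP bins are strongly correlated (the normalization couples
  them), which otherwise inflates the type-I rate; the uncorrected p is
  always kept alongside.
- The frequency factor enters RM-ANOVAs as a within-subject factor with 11
  levels (5–10 Hz). With n = 7 subjects this yields the printed interaction
  df of 50 with an error df of 300; published layouts with other error df
  (e.g. 330) cannot be uniquely reconstructed from a standard
  within-subject decomposition, so the standard decomposition is used and
  stated here. A day-subset analysis (e.g. days 1, 2, 5, 6) is a
  first-class option.

## Problem sizes in tests and the acceptance script

Monte-Carlo harnesses use the full study geometry (7-subject learning
cohorts, 6 days × 4 trials, 1024 Hz) for the discrimination and behavior
checks, 20 simulations per condition; coherence fidelity uses 20
repetitions of 100-epoch estimates per target; peak recovery uses 100
seeds. Unit tests use scaled-down cohorts (256 Hz, 2–3 subjects, 2–3 days)
where only bookkeeping, not statistical power, is under test.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the experiment — sampling, trial
schedule, spectral grid, coherence levels, learning curves — with Gaussian
narrowband rhythms and 1/f noise. It does not emulate asymmetric theta
waveforms, harmonics, movement artifacts beyond amplitude outliers,
volume conduction, electrode drift, or any pharmacology: the flat profile
is a phenomenological stand-in for a disrupted-modulation condition, not a
serotonin model. Passing tests therefore demonstrate that the estimators
and statistics recover known ground truth under realistic signal-to-noise,
not that the biological effects themselves are reproduced.

## Degenerate inputs and tie rules

Zero total band power names the offending channel; non-positive AP bins are
flagged and excluded from the log transform; identical paired samples and
zero-variance correlations raise explicit degenerate-data errors rather
than returning NaN. Argmax ties (RP peak, FCP) resolve to the lowest
frequency; quadrant-boundary points belong to the counterclockwise sector;
segment-to-quadrant assignment uses the segment midpoint, which keeps the
quadrant distances summing exactly to the path length at the cost of a
sampling-density-bounded misassignment near boundaries.
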