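# thetamaze

Analysis pipeline for multi-site theta-band EEG recorded during Morris
water-maze place learning, bundled with a synthetic-data generator that
emulates the experiment so every stage can be tested against known ground
truth — no recordings required.

## The scientific problem

During spatial learning in the rat, hippocampal theta activity (4–12 Hz)
shifts toward higher frequencies, and coherence between the medial septum
(MS) and the hippocampus rises, as the platform location is consolidated.
Recordings from four sites — supramammillary nucleus (SUM), medial septum
(MS), dentate gyrus (DG) and hippocampal field CA1 — are analyzed per trial:

- **Absolute power** `AP(f)`: mean periodogram over non-overlapping 2-s
  epochs, giving exactly 0.5 Hz resolution on the 4–12 Hz grid (17 bins);
  `nl(AP) = ln AP` for comparisons.
- **Relative power** `RP(f) = 100 · AP(f) / Σ₄₋₁₂ AP`, which removes
  amplitude differences between subjects; `Σ RP = 100` by construction.
- **Peak frequency**: argmax of RP in the 5–10 Hz band, averaged over the
  four daily trials, tracked across six training days and correlated
  between regions (Pearson).
- **Magnitude-squared coherence** per region pair,
  `msc(f) = |⟨X Y*⟩|² / (⟨|X|²⟩⟨|Y|²⟩)` over the same 2-s epochs, with the
  frequency of the coherence peak (FCP) and its magnitude.
- **Behavior**: escape latency (capped at the 60 s trial limit), path
  length, mean swim velocity, and per-quadrant distances on the day-7 probe
  trial in the 1.5 m pool.
- **Statistics**: Friedman + Wilcoxon and Mann–Whitney U for latencies,
  randomized-block ANOVA with Tukey HSD for distances/velocities,
  day × frequency repeated-measures ANOVAs for RP and coherence (optional
  Greenhouse–Geisser correction), paired t with Bonferroni, and Pearson
  peak-frequency correlations.

The generator simulates two cohorts: a control profile (`CTR`, n = 7) whose
dominant theta frequency climbs from 7 toward 8 Hz across days, with rising
septo-hippocampal coherence and shortening swim paths, and a flat profile
(`EXP`, n = 6) with none of these learning-related changes. Each EEG channel
mixes a shared narrowband theta driver, an independent same-spectrum
process and 1/f background, so pairwise coherence targets are analytic:
`msc = (SNR/(1+SNR))²` at the driver bin. Swim paths are biased correlated
random walks whose platform-bearing gain encodes learning.

## Worked example

```python
from thetamaze import SimConfig, pipeline

bundle = pipeline.run_all(SimConfig(), seed=7)

peaks = bundle.tables["daily_peaks"]
for grp in ("CTR", "EXP"):
    sel = peaks[(peaks.group == grp) & (peaks.region == "CA1")]
    by_day = sel.groupby("day").peak_freq.mean()
    print(f"{grp} CA1 mean peak frequency: day 1 = {by_day[1]:.2f} Hz, "
          f"day 6 = {by_day[6]:.2f} Hz")

rm = bundle.stats["rp_day_by_freq_CTR_CA1"]["day:freq"]
print(f"CTR CA1 day x frequency RM-ANOVA: F({rm.df[0]:.0f}, {rm.df[1]:.0f}) = "
      f"{rm.statistic:.2f}, p = {rm.p:.2e} ({rm.correction})")
```

prints (seed 7):

```
CTR CA1 mean peak frequency: day 1 = 7.00 Hz, day 6 = 8.14 Hz
EXP CA1 mean peak frequency: day 1 = 6.98 Hz, day 6 = 6.98 Hz
CTR CA1 day x frequency RM-ANOVA: F(50, 300) = 36.84, p = 1.29e-09 (GG eps=0.077)
```

The control cohort's theta peak has moved up by more than one 0.5 Hz bin and
the day × frequency interaction is overwhelming, while the flat cohort's
peak has not moved. The same bundle carries the coherence, behavior and
probe tables; for instance the CTR group's MS–CA1 coherence at 8 Hz rises
from 0.24 (day 1) to 0.75 (day 6), mean escape latency falls from 37.5 s to
3.7 s, and on the probe trial the CTR group concentrates 7.06 m of swimming
in the platform (N) quadrant versus at most 0.30 m in any other quadrant.

The same run is available from the shell:

```sh
thetamaze simulate --out sim/ --seed 7          # write the raw cohort as TSV
thetamaze analyze  --data sim/ --out analysis/  # spectra, coherence, behavior
thetamaze stats    --table analysis/spectra.tsv --out rm.tsv --days 1,2,5,6
thetamaze report   --out report/ --seed 7       # everything in one step
```

All commands accept `--config cfg.yaml`; keys mirror `SimConfig` and omitted
keys keep their defaults:

```yaml
fs: 1024.0                       # sampling rate [Hz]; fs * 2 s must be integer
n_subjects: {CTR: 7, EXP: 6}     # subjects per group
days: 6                          # training days (day 7 is the probe)
trials_per_day: 4
peak_schedule:                   # dominant theta frequency per day [Hz]
  CTR: [7.0, 7.25, 7.5, 7.5, 7.75, 8.0]
  EXP: [7.0, 7.0, 7.0, 7.0, 7.0, 7.0]
coupling:                        # target MSC per region pair and day
  CA1-MS: {CTR: [0.30, 0.37, 0.44, 0.51, 0.58, 0.65], EXP: [0.30, 0.30, 0.30, 0.30, 0.30, 0.30]}
oscillator_bandwidth: 0.5        # spectral width of the theta peak [Hz]
snr: 3.0                         # theta-to-background power ratio in 4-12 Hz
bias_schedule:                   # platform-bearing gain of the swim walk
  CTR: [0.05, 0.10, 0.20, 0.30, 0.50, 0.70]
  EXP: [0.08, 0.08, 0.08, 0.08, 0.08, 0.08]
```

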