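# taprhythm

Analysis toolkit for **auditory-motor synchronization (finger-tapping)
experiments** in which participants tap along with metronome sequences whose
tempo is constant (isochronous), ramps predictably (tempo change), or varies
unpredictably (random). It is written for timing researchers who need a
tested, reproducible implementation of:

- **pacing-stimulus generation** under the standard constraints: 48-tone
  trials with a 4-tone ready cue, base inter-onset interval (IOI) 500 ms,
  triangle-wave tempo changes between 400 and 600 ms (six alternating ramps
  of 4, 6 or 8 beats, starting and ending with a decrease), jittered
  initial/final isochronous beats, and an exactly conserved 500 ms mean IOI
  in all conditions;
- **tap-beat alignment**: each tap is scored against the nearest beat within
  half a local IOI (a greedy global assignment), the first 3 taps are dropped
  as a start-up transient, and the signed **asynchrony** (tap − beat; negative
  = anticipation) is summarised per trial as mean and sample SD;
- the **prediction/tracking ratio**: with ITI the inter-tap interval,

  `ratio = r_lag0 / r_lag1`,  where `r_lagk = corr(ITI[n], IOI[n−k])`.

  A ratio > 1 means the tapper *predicts* upcoming intervals (current ITI
  matches current IOI); < 1 means they *track* past ones. Both raw
  correlations are bounded below by the sequence's lag-1 autocorrelation, so
  the ratio cancels the sequence-specific limit. Runs of ≤ 3 missed taps are
  interpolated to keep ITI and IOI counts equal; trials with > 3 consecutive
  misses are excluded;
- a **generative tapper simulator** (prediction weight `w`, linear phase
  correction `α`, anticipation bias, Wing–Kristofferson-style timekeeper +
  motor noise, missed taps) that serves as the synthetic cohort for testing
  every pipeline stage;
- **group statistics**: one-way repeated-measures ANOVA with Mauchly's test,
  Greenhouse–Geisser correction and generalized eta squared, plus Pearson
  correlation tests (`r`, `t`, `df = n − 2`, two-sided `p`).

## Worked example

```python
import taprhythm as tr

spec = tr.CohortSpec(n_participants=6, trials_per_condition=4, root_seed=42)
dataset = tr.simulate_cohort(spec)                  # taps + sequences + ground truth
result = tr.SynchronyModel.from_dataset(dataset).fit()
print(result.summary())
```

prints

```
Auditory-motor synchronization analysis
======================================================
participants: 6   trials: 72   config: a280bb424343
0 out of 24 tempo-change trials (0.0%) excluded (>3 consecutive missed taps); 37.5% of tempo-change trials had matched ITI/IOI counts without interpolation; 72 trials = 72 scored + 0 excluded + 0 degenerate

Per-condition asynchrony (cohort means):
  isochronous   mean =    -78.9 ms   SD =   13.2 ms
  tempo_change  mean =    -77.3 ms   SD =   28.6 ms
  random        mean =    -78.5 ms   SD =   34.1 ms

Prediction/tracking ratio (median over valid tempo-change trials):
  median 1.055   range [0.946, 1.105]   n = 6

SD of asynchronies across conditions: F(1.04, 5.18) = 13.64, p = 0.01297, eta_G^2 = 0.396 (GG eps = 0.518)
ratio vs isochronous mean asynchrony: r(4) = 0.984, p = 0.0003987, r^2 = 0.968
ratio vs isochronous SD of asynchronies: r(4) = -0.950, p = 0.003718, r^2 = 0.902
```

Reading the output: taps anticipate beats by ~80 ms (the negative mean
asynchrony typical of synchronization tapping); tapping variability rises as
the pacing sequence becomes less predictable (isochronous < tempo change <
random, confirmed by the repeated-measures ANOVA with Greenhouse–Geisser
corrected degrees of freedom); and tappers with higher prediction/tracking
ratios tap both more accurately (less negative mean asynchrony, positive
correlation) and more precisely (smaller SD, negative correlation) to the
isochronous beat.

`result.trial_table` and `result.participant_table` hold the per-trial and
per-participant values; `result.plot_ratio_scatter(...)` and
`result.plot_condition_sd()` draw the standard figures.

The same pipeline runs from the shell on CSV tap logs:

```bash
taprhythm simulate --seed 42 --n-participants 6 --trials-per-condition 4 --out data/
taprhythm score    --sequences data/ --taps data/taps.csv --out scored/
taprhythm report   --results data/ --out report/
```

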